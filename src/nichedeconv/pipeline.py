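"""End-to-end orchestration: simulate -> preprocess -> train -> deconvolute -> stats.

A :class:`RunConfig` (round-trippable through YAML) drives the stages; a
single master seed deterministically derives every stage seed, so a run is
reproducible bit-for-bit from its config.  Each run writes a manifest with
SHA-256 checksums of every output so identical config+seed can be verified
to yield identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .forest import (
    ForestConfig,
    ForestModel,
    composition_table,
    evaluate_forest,
    predict_niche_composition,
    stratified_split,
    train_random_forest,
)
from .matrix import (
    ProteinMatrix,
    read_matrix_gct,
    read_matrix_tsv,
    read_sample_meta_tsv,
    write_matrix_tsv,
    write_sample_meta_tsv,
)
from .preprocess import (
    ImputationParams,
    filter_by_group_presence,
    impute_downshifted_gaussian,
    intersect_features,
    zscore_within_sample,
)
from .stats import VolcanoParams, chi_squared_niche_enrichment, pca_embedding, sam_test
from .synthetic import (
    BulkCohort,
    ReferenceAtlas,
    SimConfig,
    generate_bulk_cohort,
    generate_reference_atlas,
    write_truth_json,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "deconvolute", "stats")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed = truncated SHA-256 of (master seed, stage name), < 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Full-run configuration; one master seed derives all stage seeds."""

    outdir: str = "runs/run"
    stages: tuple[str, ...] = STAGES
    master_seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    imputation: ImputationParams = field(default_factory=ImputationParams)
    forest: ForestConfig = field(default_factory=ForestConfig)
    volcano: VolcanoParams = field(default_factory=VolcanoParams)
    min_presence_frac: float = 0.6
    enrichment_focus: tuple[str, str] = ("proneural", "IT")

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["enrichment_focus"] = list(self.enrichment_focus)
        d["sim"]["subtype_coupling"] = {
            k: list(v) for k, v in dict(self.sim.subtype_coupling).items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "subtype_coupling" in sim:
            sim["subtype_coupling"] = {
                k: (v[0], float(v[1])) for k, v in sim["subtype_coupling"].items()
            }
        return cls(
            outdir=d.get("outdir", "runs/run"),
            stages=tuple(d.get("stages", STAGES)),
            master_seed=int(d.get("master_seed", 0)),
            sim=SimConfig(**sim),
            imputation=ImputationParams(**d.get("imputation", {})),
            forest=ForestConfig(**d.get("forest", {})),
            volcano=VolcanoParams(**d.get("volcano", {})),
            min_presence_frac=float(d.get("min_presence_frac", 0.6)),
            enrichment_focus=tuple(d.get("enrichment_focus", ("proneural", "IT"))),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class DependencyError(RuntimeError):
    """A stage is missing the artifacts of a required predecessor."""


def _require(path: Path, stage: str, predecessor: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} requires {path.name} from stage {predecessor!r}; "
            f"run {predecessor!r} first"
        )
    return path


def preprocess_pair(
    atlas: ReferenceAtlas,
    bulk: BulkCohort,
    imputation: ImputationParams,
    min_frac: float = 0.6,
) -> tuple[ReferenceAtlas, BulkCohort]:
    """Filter/impute both datasets, intersect features, z-score per sample.

    Z-scoring happens after feature intersection so both datasets are
    standardized over the same protein set — the cross-platform
    harmonization step.
    """
    a = filter_by_group_presence(atlas.matrix, atlas.niche_of_sample, min_frac)
    if a.has_missing():
        a = impute_downshifted_gaussian(a, imputation)
    else:
        a.scale_tag = "log2-imputed"
    b = filter_by_group_presence(bulk.matrix, bulk.subtype_of_sample, min_frac)
    if b.has_missing():
        b = impute_downshifted_gaussian(
            b, dataclasses.replace(imputation, seed=imputation.seed + 1)
        )
    else:
        b.scale_tag = "log2-imputed"
    a, b = intersect_features(a, b)
    a = zscore_within_sample(a)
    b = zscore_within_sample(b)
    atlas_p = ReferenceAtlas(
        matrix=a, niche_of_sample=atlas.niche_of_sample.loc[a.sample_ids], truth=atlas.truth
    )
    bulk_p = BulkCohort(
        matrix=b,
        subtype_of_sample=bulk.subtype_of_sample.loc[b.sample_ids],
        true_weights=bulk.true_weights,
    )
    return atlas_p, bulk_p


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order and write a run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": config.master_seed,
        "stages": list(config.stages),
        "stage_seeds": {s: derive_seed(config.master_seed, s) for s in STAGES},
        "outputs": {},
    }
    config.to_yaml(out / "config.yaml")

    atlas: ReferenceAtlas | None = None
    bulk: BulkCohort | None = None
    atlas_p: ReferenceAtlas | None = None
    bulk_p: BulkCohort | None = None
    model: ForestModel | None = None
    comps = None

    def record(stage: str, *paths: Path) -> None:
        manifest["outputs"].setdefault(stage, {})
        for p in paths:
            manifest["outputs"][stage][p.name] = _sha256(p)

    if "simulate" in config.stages:
        sim = dataclasses.replace(config.sim, seed=derive_seed(config.master_seed, "simulate"))
        atlas = generate_reference_atlas(sim)
        bulk = generate_bulk_cohort(atlas, sim)
        write_matrix_tsv(atlas.matrix, out / "atlas.tsv")
        write_sample_meta_tsv(atlas.matrix, out / "atlas_meta.tsv")
        write_truth_json(atlas, out / "atlas_truth.json")
        write_matrix_tsv(bulk.matrix, out / "bulk.tsv")
        write_sample_meta_tsv(bulk.matrix, out / "bulk_meta.tsv")
        bulk.true_weights.to_csv(out / "bulk_true_weights.tsv", sep="\t")
        record(
            "simulate",
            out / "atlas.tsv",
            out / "atlas_meta.tsv",
            out / "bulk.tsv",
            out / "bulk_meta.tsv",
            out / "bulk_true_weights.tsv",
        )

    if "preprocess" in config.stages:
        if atlas is None or bulk is None:
            a_path = _require(out / "atlas.tsv", "preprocess", "simulate")
            meta = read_sample_meta_tsv(out / "atlas_meta.tsv")
            m = read_matrix_tsv(a_path, sample_meta=meta, scale_tag="log2")
            atlas = ReferenceAtlas(matrix=m, niche_of_sample=meta["group"])
            b_path = _require(out / "bulk.tsv", "preprocess", "simulate")
            bmeta = read_sample_meta_tsv(out / "bulk_meta.tsv")
            bm = read_matrix_tsv(b_path, sample_meta=bmeta, scale_tag="log2")
            bulk = BulkCohort(matrix=bm, subtype_of_sample=bmeta["group"])
        imput = dataclasses.replace(
            config.imputation, seed=derive_seed(config.master_seed, "preprocess")
        )
        atlas_p, bulk_p = preprocess_pair(atlas, bulk, imput, config.min_presence_frac)
        write_matrix_tsv(atlas_p.matrix, out / "atlas_proc.tsv")
        write_matrix_tsv(bulk_p.matrix, out / "bulk_proc.tsv")
        record("preprocess", out / "atlas_proc.tsv", out / "bulk_proc.tsv")

    if "train" in config.stages:
        if atlas_p is None:
            a_path = _require(out / "atlas_proc.tsv", "train", "preprocess")
            meta = read_sample_meta_tsv(out / "atlas_meta.tsv")
            m = read_matrix_tsv(a_path, sample_meta=meta, scale_tag="zscored")
            atlas_p = ReferenceAtlas(matrix=m, niche_of_sample=meta["group"])
        split_seed = derive_seed(config.master_seed, "train")
        region = (
            atlas_p.matrix.sample_meta["region"]
            if config.forest.split_by == "region"
            and "region" in atlas_p.matrix.sample_meta.columns
            else None
        )
        train_ids, test_ids = stratified_split(
            atlas_p.niche_of_sample, config.forest.train_frac, split_seed, region
        )
        fc = dataclasses.replace(config.forest, seed=split_seed)
        train_atlas = ReferenceAtlas(
            matrix=atlas_p.matrix.subset_samples(train_ids),
            niche_of_sample=atlas_p.niche_of_sample.loc[train_ids],
            truth=atlas_p.truth,
        )
        test_atlas = ReferenceAtlas(
            matrix=atlas_p.matrix.subset_samples(test_ids),
            niche_of_sample=atlas_p.niche_of_sample.loc[test_ids],
            truth=atlas_p.truth,
        )
        model = train_random_forest(train_atlas, fc)
        model.save(out / "model")
        report = evaluate_forest(model, test_atlas)
        report.confusion.to_csv(out / "confusion.tsv", sep="\t")
        (out / "auc.json").write_text(
            json.dumps(
                {
                    "macro_auc": report.auc,
                    "per_class_auc": report.per_class_auc.to_dict(),
                    "n_train": len(train_ids),
                    "n_test": len(test_ids),
                },
                indent=2,
            )
        )
        record("train", out / "confusion.tsv", out / "auc.json")

    if "deconvolute" in config.stages:
        if model is None:
            _require(out / "model" / "manifest.json", "deconvolute", "train")
            model = ForestModel.load(out / "model")
        if bulk_p is None:
            b_path = _require(out / "bulk_proc.tsv", "deconvolute", "preprocess")
            bmeta = read_sample_meta_tsv(out / "bulk_meta.tsv")
            bm = read_matrix_tsv(b_path, sample_meta=bmeta, scale_tag="zscored")
            bulk_p = BulkCohort(matrix=bm, subtype_of_sample=bmeta["group"])
        comps = predict_niche_composition(model, bulk_p)
        table = composition_table(comps)
        table.to_csv(out / "compositions.tsv", sep="\t", index=False, float_format="%.10g")
        from .plots import stacked_bar_composition

        stacked_bar_composition(table, out / "compositions.png")
        record("deconvolute", out / "compositions.tsv")

    if "stats" in config.stages:
        if comps is None or bulk_p is None:
            c_path = _require(out / "compositions.tsv", "stats", "deconvolute")
            table = pd.read_csv(c_path, sep="\t")
            b_path = _require(out / "bulk_proc.tsv", "stats", "preprocess")
            bmeta = read_sample_meta_tsv(out / "bulk_meta.tsv")
            bm = read_matrix_tsv(b_path, sample_meta=bmeta, scale_tag="zscored")
            bulk_p = BulkCohort(matrix=bm, subtype_of_sample=bmeta["group"])
            dominant = (
                table[table["dominant"]].set_index("sample")["niche"]
            )
        else:
            dominant = pd.Series(
                {c.sample_id: c.dominant for c in comps}, name="niche"
            )
        subtype = bulk_p.subtype_of_sample
        tumor = subtype.index[subtype != "normal"]
        enrich = chi_squared_niche_enrichment(
            dominant.loc[tumor], subtype.loc[tumor], focus=config.enrichment_focus
        )
        (out / "enrichment.json").write_text(
            json.dumps(
                {
                    "observed": enrich.observed.to_dict(),
                    "expected": enrich.expected.round(6).to_dict(),
                    "chi2": enrich.chi2,
                    "df": enrich.df,
                    "p_value": enrich.p_value,
                    "focus": list(config.enrichment_focus),
                    "focus_chi2": enrich.focus_chi2,
                    "focus_p": enrich.focus_p,
                },
                indent=2,
            )
        )
        # volcano between the two most common dominant niches among tumors
        counts = dominant.loc[tumor].value_counts()
        vol_params = dataclasses.replace(
            config.volcano, seed=derive_seed(config.master_seed, "stats")
        )
        if len(counts) >= 2 and counts.iloc[1] >= 2:
            g1 = dominant.loc[tumor][dominant.loc[tumor] == counts.index[0]].index.tolist()
            g2 = dominant.loc[tumor][dominant.loc[tumor] == counts.index[1]].index.tolist()
            vol = sam_test(bulk_p.matrix, g1, g2, vol_params)
            vol.table.to_csv(out / "volcano.tsv", sep="\t", float_format="%.10g")
        scores, evr = pca_embedding(bulk_p.matrix)
        scores.assign(explained_pc1=evr[0], explained_pc2=evr[1]).to_csv(
            out / "pca.tsv", sep="\t", float_format="%.10g"
        )
        record("stats", out / "enrichment.json", out / "pca.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def ingest_external_matrix(
    path: str | Path,
    format: str = "tsv",
    id_column: str | None = None,
    platform_tag: str = "unknown",
    scale_tag: str = "raw",
) -> ProteinMatrix:
    """Read a user-supplied abundance matrix (TSV or GCT 1.2).

    The scale tag comes from configuration, never guessed from the data.
    Duplicate gene symbols are resolved by keeping the row with the highest
    median abundance (logged); duplicate sample ids are an error.
    """
    path = Path(path)
    if format == "gct":
        raw = read_matrix_gct(path, scale_tag=scale_tag)
        frame = raw.values
    elif format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        dup_cols = pd.Index(header).duplicated()
        if dup_cols.any():
            dups = pd.Index(header)[dup_cols].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        frame = pd.read_csv(path, sep="\t")
        id_col = id_column or frame.columns[0]
        frame = frame.set_index(id_col)
        frame.index = frame.index.astype(str)
    else:
        raise ValueError(f"unknown format {format!r}")

    if frame.columns.duplicated().any():
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    if frame.index.duplicated().any():
        medians = frame.median(axis=1)
        keep = (
            pd.DataFrame({"median": medians})
            .assign(pos=range(len(frame)))
            .sort_values(["median"], ascending=False)
            .groupby(level=0, sort=False)["pos"]
            .first()
            .sort_values()
        )
        n_dropped = len(frame) - len(keep)
        logger.warning(
            "resolved %d duplicate gene symbols by highest median abundance", n_dropped
        )
        frame = frame.iloc[keep.to_numpy()]

    meta = pd.DataFrame(
        {"platform": platform_tag}, index=pd.Index(frame.columns, name="sample_id")
    )
    return ProteinMatrix(values=frame, sample_meta=meta, scale_tag=scale_tag)
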