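"""Synthetic reference atlases and bulk mixture cohorts with known ground truth.

The generator emulates the structure of a laser-capture-microdissected
glioblastoma proteome atlas and a bulk proteogenomic tumor cohort:

* a **reference atlas** of microdissected regions, each labelled with one of
  the five histomorphologic niches (LE, IT, CT, MVP, PAN).  Each niche has a
  set of signature proteins elevated by a fixed log2 effect; regions from the
  same patient share a per-protein random intercept; each region is measured
  as technical duplicates; low-intensity values are censored (missing not at
  random), reproducing the left-shifted missingness that downshifted-Gaussian
  imputation assumes.  The scale mimics log2 label-free (LFQ) intensities.
* a **bulk cohort** whose samples are Dirichlet mixtures of the five niche
  mean profiles, with per-subtype tilting of the Dirichlet concentration
  (e.g. proneural samples drawn with elevated infiltrating-tumor weight) and
  a global affine platform shift so the bulk scale differs from the
  reference scale, as a TMT cohort differs from an LFQ atlas.

Mixing acts on log-scale profiles (weighted arithmetic mean of
log-intensities): the classifier consumes log/z-scored data, so the mixture
is defined on the scale the model sees.

Ground truth (niche mean profiles, marker sets, true mixture weights) is
recorded so every downstream stage is testable without external downloads.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ProteinMatrix, write_matrix_tsv, write_sample_meta_tsv
from .niches import NICHES, SUBTYPES

_CENSOR_PROXY_SD = 0.5  # SD of the noise added to intensities before thresholding

DEFAULT_SUBTYPE_COUNTS: dict[str, int] = {
    "proneural": 22,
    "classical": 26,
    "mesenchymal": 38,
    "IDH-mutant": 14,
    "normal": 10,
}

DEFAULT_SUBTYPE_COUPLING: dict[str, tuple[str, float]] = {
    "proneural": ("IT", 4.0),
    "IDH-mutant": ("IT", 4.0),
    "mesenchymal": ("MVP", 4.0),
}


@dataclass
class SimConfig:
    """Generative parameters for the synthetic atlas and bulk cohort.

    Attributes
    ----------
    n_proteins
        Proteins quantified across the atlas (default 4794).
    n_patients, n_regions, duplicates_per_region
        20 patients contribute ``n_regions`` microdissected regions (each a
        patient x niche combination; default 78, i.e. not every patient yields
        every niche), measured as technical duplicates — 156 columns at the
        defaults.
    n_signature_per_niche, signature_effect
        Marker proteins per niche and their log2 elevation within that niche.
    patient_sd, noise_sd
        Between-patient and residual SDs, log2 units.
    missing_censor_quantile
        Fraction of low-intensity values censored (MNAR), via a noisy
        intensity proxy thresholded at this matrix-wide quantile.
    n_bulk, dirichlet_alpha, subtype_coupling, subtype_counts
        Bulk cohort size, base Dirichlet concentration over the five niches
        (scalar or per-niche mapping; ``inf`` for a niche collapses to weight
        1 on it), and the subtype -> (niche, factor) coupling that multiplies
        that niche's concentration for samples of that subtype.
    platform_scale, platform_offset
        Affine shift ``a*x + b`` applied to bulk values so the bulk scale
        differs from the reference scale and z-score harmonization matters.
    """

    n_proteins: int = 4794
    n_patients: int = 20
    n_regions: int | None = 78
    duplicates_per_region: int = 2
    n_signature_per_niche: int = 150
    signature_effect: float = 3.0
    patient_sd: float = 0.5
    noise_sd: float = 0.5
    missing_censor_quantile: float = 0.1
    n_bulk: int = 110
    dirichlet_alpha: float | Mapping[str, float] = 0.5
    subtype_coupling: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_COUPLING)
    )
    subtype_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS)
    )
    base_mean: float = 25.0
    base_sd: float = 2.0
    platform_scale: float = 0.8
    platform_offset: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_patients", "duplicates_per_region", "n_bulk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_regions is not None and self.n_regions <= 0:
            raise ValueError("n_regions must be > 0 (or None for all)")
        if self.patient_sd < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not (0 <= self.missing_censor_quantile < 1):
            raise ValueError("missing_censor_quantile must lie in [0, 1)")
        if 5 * self.n_signature_per_niche > self.n_proteins:
            raise ValueError(
                "n_signature_per_niche x 5 exceeds n_proteins; "
                "marker sets must be disjoint"
            )
        for subtype, (niche, factor) in dict(self.subtype_coupling).items():
            if niche not in NICHES:
                raise ValueError(f"coupling for {subtype!r} names unknown niche {niche!r}")
            if factor <= 0:
                raise ValueError("coupling factors must be > 0")

    def resolved_subtype_counts(self) -> dict[str, int]:
        """Subtype counts rescaled to ``n_bulk`` (largest-remainder rounding)."""
        counts = dict(self.subtype_counts)
        total = sum(counts.values())
        if total == self.n_bulk:
            return counts
        quotas = {s: c * self.n_bulk / total for s, c in counts.items()}
        out = {s: int(np.floor(q)) for s, q in quotas.items()}
        leftover = self.n_bulk - sum(out.values())
        for s in sorted(quotas, key=lambda s: quotas[s] - np.floor(quotas[s]), reverse=True)[:leftover]:
            out[s] += 1
        return out

    def alpha_vector(self) -> np.ndarray:
        if isinstance(self.dirichlet_alpha, Mapping):
            alpha = np.array([float(self.dirichlet_alpha[n]) for n in NICHES])
        else:
            alpha = np.full(len(NICHES), float(self.dirichlet_alpha))
        if np.any(alpha <= 0) and not np.any(np.isinf(alpha)):
            raise ValueError("dirichlet_alpha entries must be > 0")
        return alpha


@dataclass
class ReferenceAtlas:
    """Niche-labelled reference matrix plus (synthetic only) generative truth."""

    matrix: ProteinMatrix
    niche_of_sample: pd.Series
    truth: dict | None = None

    def __post_init__(self) -> None:
        labels = set(self.niche_of_sample.unique())
        missing = set(NICHES) - labels
        if missing:
            raise ValueError(f"atlas lacks niches: {sorted(missing)}")
        if not self.niche_of_sample.index.equals(self.matrix.sample_ids):
            self.niche_of_sample = self.niche_of_sample.loc[self.matrix.sample_ids]


@dataclass
class BulkCohort:
    """Bulk mixture cohort with subtype labels and (synthetic only) true weights."""

    matrix: ProteinMatrix
    subtype_of_sample: pd.Series
    true_weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.true_weights is not None:
            w = self.true_weights.to_numpy()
            if np.any(w < 0) or np.any(np.abs(w.sum(axis=1) - 1) > 1e-9):
                raise ValueError("true_weights rows must be non-negative and sum to 1")


@dataclass
class SpikeRecord:
    """Book-keeping for spiked differential proteins (recovery scoring)."""

    proteins: list[str]
    samples: list[str]
    delta: float


def _atlas_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))


def _bulk_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))


def _select_regions(config: SimConfig, rng: np.random.Generator) -> list[tuple[int, str]]:
    """Pick patient x niche regions; every niche keeps at least 2 regions."""
    combos = [(p, n) for p in range(config.n_patients) for n in NICHES]
    if config.n_regions is None or config.n_regions >= len(combos):
        return combos
    if config.n_regions < 2 * len(NICHES):
        raise ValueError("n_regions too small to give every niche >= 2 regions")
    for _ in range(1000):
        idx = rng.choice(len(combos), size=config.n_regions, replace=False)
        chosen = [combos[i] for i in sorted(idx)]
        counts = pd.Series([n for _, n in chosen]).value_counts()
        if all(counts.get(n, 0) >= 2 for n in NICHES):
            return chosen
    raise RuntimeError("could not select regions covering all niches")


def generate_reference_atlas(config: SimConfig) -> ReferenceAtlas:
    """Simulate a niche-labelled reference atlas on a log2-intensity-like scale.

    Per-protein baselines are drawn once; each niche elevates its marker set
    by ``signature_effect``; regions from one patient share per-protein random
    intercepts; technical duplicates differ only in residual noise; values
    whose noisy intensity proxy falls below the matrix-wide
    ``missing_censor_quantile`` are censored to missing.
    """
    rng = _atlas_rng(config)
    p = config.n_proteins
    protein_ids = pd.Index([f"PROT{i:05d}" for i in range(p)], name="gene_symbol")

    baseline = rng.normal(config.base_mean, config.base_sd, size=p)
    marker_pool = rng.choice(p, size=5 * config.n_signature_per_niche, replace=False)
    markers = {
        niche: np.sort(marker_pool[i * config.n_signature_per_niche : (i + 1) * config.n_signature_per_niche])
        for i, niche in enumerate(NICHES)
    }
    niche_means = np.tile(baseline, (len(NICHES), 1))
    for i, niche in enumerate(NICHES):
        niche_means[i, markers[niche]] += config.signature_effect

    patient_effect = rng.normal(0.0, config.patient_sd, size=(config.n_patients, p))
    regions = _select_regions(config, rng)

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for patient, niche in regions:
        base = niche_means[NICHES.index(niche)] + patient_effect[patient]
        for rep in range(config.duplicates_per_region):
            x = base + rng.normal(0.0, config.noise_sd, size=p)
            sid = f"P{patient:02d}_{niche}_r{rep + 1}"
            columns.append(x)
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient": f"P{patient:02d}",
                    "group": niche,
                    "region": f"P{patient:02d}_{niche}",
                    "platform": "LFQ",
                }
            )

    values = np.column_stack(columns)
    # MNAR censoring: threshold a noisy intensity proxy at the matrix-wide
    # quantile.  The proxy is always drawn so the same seed yields the same
    # censoring geometry at every quantile (monotone in the quantile).
    proxy = values + rng.normal(0.0, _CENSOR_PROXY_SD, size=values.shape)
    if config.missing_censor_quantile > 0:
        threshold = np.quantile(proxy, config.missing_censor_quantile)
        values = np.where(proxy < threshold, np.nan, values)

    frame = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = ProteinMatrix(values=frame, sample_meta=meta, scale_tag="log2")
    truth = {
        "baseline": pd.Series(baseline, index=protein_ids),
        "niche_means": pd.DataFrame(niche_means, index=list(NICHES), columns=protein_ids),
        "markers": {n: protein_ids[idx].tolist() for n, idx in markers.items()},
        "config": config,
    }
    return ReferenceAtlas(matrix=matrix, niche_of_sample=meta["group"], truth=truth)


def _draw_weights(
    subtype: str, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if subtype == "normal":
        w = np.zeros(len(NICHES))
        w[NICHES.index("LE")] = 1.0
        return w
    alpha = config.alpha_vector().copy()
    coupling = dict(config.subtype_coupling).get(subtype)
    if coupling is not None:
        niche, factor = coupling
        alpha[NICHES.index(niche)] *= factor
    if np.any(np.isinf(alpha)):
        w = np.zeros(len(NICHES))
        w[int(np.argmax(np.isinf(alpha)))] = 1.0
        return w
    return rng.dirichlet(alpha)


def generate_bulk_cohort(atlas: ReferenceAtlas, config: SimConfig) -> BulkCohort:
    """Simulate a bulk cohort as Dirichlet mixtures of the atlas niche profiles.

    Requires a synthetic atlas (``truth`` present).  Each sample's expected
    log-profile is the weight-averaged niche mean profile; subtype coupling
    tilts the Dirichlet concentration; normal-brain controls get weight 1 on
    LE; an affine platform shift moves the cohort onto a TMT-like scale.
    """
    if atlas.truth is None:
        raise ValueError("bulk generation requires an atlas with generative truth")
    rng = _bulk_rng(config)
    niche_means = atlas.truth["niche_means"].to_numpy()
    protein_ids = atlas.truth["niche_means"].columns

    counts = config.resolved_subtype_counts()
    unknown = set(counts) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unknown subtypes in subtype_counts: {sorted(unknown)}")

    subtypes = [s for s in SUBTYPES if s in counts for _ in range(counts[s])]
    sample_ids = [f"B{i:03d}" for i in range(config.n_bulk)]

    weights = np.vstack([_draw_weights(s, config, rng) for s in subtypes])
    expected = weights @ niche_means
    values = expected + rng.normal(0.0, config.noise_sd, size=expected.shape)
    values = config.platform_scale * values + config.platform_offset

    frame = pd.DataFrame(values.T, index=protein_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"patient": sample_ids, "group": subtypes, "platform": "TMT"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ProteinMatrix(values=frame, sample_meta=meta, scale_tag="log2")
    true_weights = pd.DataFrame(weights, index=sample_ids, columns=list(NICHES))
    return BulkCohort(
        matrix=matrix,
        subtype_of_sample=meta["group"],
        true_weights=true_weights,
    )


def spike_differential(
    matrix: ProteinMatrix,
    group_a: Sequence[str],
    proteins: Sequence[str],
    delta: float,
) -> tuple[ProteinMatrix, SpikeRecord]:
    """Add ``delta`` (log2 units) to the named proteins in group A's samples.

    Returns the spiked copy and a record of the spiked set for recovery
    scoring.  An empty protein set returns an unchanged copy with a warning.
    """
    group_a = list(group_a)
    proteins = list(proteins)
    missing_s = set(group_a) - set(matrix.sample_ids)
    if missing_s:
        raise KeyError(f"samples not in matrix: {sorted(missing_s)[:5]}")
    missing_p = set(proteins) - set(matrix.protein_ids)
    if missing_p:
        raise KeyError(f"proteins not in matrix: {sorted(missing_p)[:5]}")
    out = matrix.copy()
    if not proteins:
        warnings.warn("spike_differential called with an empty protein set")
        return out, SpikeRecord(proteins=[], samples=group_a, delta=delta)
    out.values.loc[proteins, group_a] += delta
    return out, SpikeRecord(proteins=proteins, samples=group_a, delta=delta)


def write_truth_json(atlas: ReferenceAtlas, path: str | Path) -> None:
    """Persist atlas ground truth (marker sets and niche means) as JSON."""
    if atlas.truth is None:
        raise ValueError("atlas carries no truth")
    payload = {
        "markers": atlas.truth["markers"],
        "niche_means": {
            n: atlas.truth["niche_means"].loc[n].round(6).to_dict() for n in NICHES
        },
    }
    Path(path).write_text(json.dumps(payload))


def write_atlas(atlas: ReferenceAtlas, prefix: str | Path) -> None:
    """Write atlas matrix + metadata (+ truth) TSV/JSON under a path prefix."""
    prefix = Path(prefix)
    write_matrix_tsv(atlas.matrix, prefix.with_suffix(".tsv"))
    write_sample_meta_tsv(atlas.matrix, prefix.parent / (prefix.name + "_meta.tsv"))
    if atlas.truth is not None:
        write_truth_json(atlas, prefix.parent / (prefix.name + "_truth.json"))
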