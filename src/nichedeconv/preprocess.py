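"""Perseus-style matrix preprocessing and cross-dataset harmonization.

The classification pipeline consumes matrices prepared the way proteomics
practitioners prepare label-free data: keep proteins quantified in at least
60% of the samples of some annotation group, log2-transform, impute missing
(left-censored) values from a downshifted Gaussian, and z-score each sample
so reference (LFQ-like) and bulk (TMT-like) datasets land on a comparable
scale before classification.

Two imputation presets ship: the printed parameterization
(``downshift=0.3, width=1.8``) and the conventional Perseus default
(``downshift=1.8, width=0.3``); the two are plausibly transposed in the
literature, so both are first-class and neither is asserted as correct.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ProteinMatrix

logger = logging.getLogger(__name__)


@dataclass
class ImputationParams:
    """Downshifted-Gaussian imputation parameters, in sample-SD units.

    Missing entries of sample *j* are drawn from
    ``Normal(m_j - downshift * s_j, (width * s_j)^2)`` where ``m_j`` and
    ``s_j`` are the mean and SD of the sample's observed values
    (``scope='global'`` uses matrix-wide moments instead).
    """

    downshift: float = 0.3
    width: float = 1.8
    scope: str = "per_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")
        if self.scope not in ("per_sample", "global"):
            raise ValueError("scope must be 'per_sample' or 'global'")

    @classmethod
    def perseus_convention(cls, scope: str = "per_sample", seed: int = 0) -> "ImputationParams":
        """The conventional Perseus defaults (downshift 1.8, width 0.3)."""
        return cls(downshift=1.8, width=0.3, scope=scope, seed=seed)


def filter_by_group_presence(
    matrix: ProteinMatrix,
    group_of_sample: pd.Series | dict,
    min_frac: float = 0.6,
) -> ProteinMatrix:
    """Keep proteins observed in >= ``min_frac`` of the samples of some group.

    The threshold is inclusive: a protein present in exactly 60% of one
    group's samples is retained at the default.  Row order is preserved.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must lie in (0, 1]")
    groups = pd.Series(group_of_sample)
    groups = groups.loc[matrix.sample_ids]
    if groups.isna().any():
        raise ValueError("every sample must be assigned to exactly one group")

    observed = matrix.values.notna()
    keep = pd.Series(False, index=matrix.protein_ids)
    for g, cols in groups.groupby(groups).groups.items():
        if len(cols) == 0:
            raise ValueError(f"group {g!r} has zero samples")
        frac = observed[list(cols)].mean(axis=1)
        keep |= frac >= min_frac
    out = matrix.subset_proteins(matrix.protein_ids[keep])
    logger.info(
        "presence filter (>=%.0f%% in a group): %d -> %d proteins",
        100 * min_frac,
        matrix.n_proteins,
        out.n_proteins,
    )
    return out


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Elementwise log2 of a raw-intensity matrix; missing stays missing."""
    if matrix.scale_tag != "raw":
        raise ValueError(f"log2_transform expects scale_tag 'raw', got {matrix.scale_tag!r}")
    vals = matrix.values
    bad = (vals <= 0).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at protein {vals.index[i]!r}, "
            f"sample {vals.columns[j]!r}"
        )
    out = matrix.with_values(np.log2(vals))
    out.scale_tag = "log2"
    return out


def impute_downshifted_gaussian(
    matrix: ProteinMatrix, params: ImputationParams | None = None
) -> ProteinMatrix:
    """Replace missing values with draws from a downshifted Gaussian.

    Observed entries are never altered; the imputation is seeded and
    reproducible.  A sample with fewer than two observed values falls back
    to matrix-wide moments with a logged warning.
    """
    params = params or ImputationParams()
    if matrix.scale_tag not in ("log2",):
        raise ValueError(
            f"imputation expects scale_tag 'log2', got {matrix.scale_tag!r}"
        )
    rng = np.random.default_rng(params.seed)
    vals = matrix.values.to_numpy(copy=True)
    flat = vals[~np.isnan(vals)]
    g_mean = float(np.mean(flat)) if flat.size else 0.0
    g_sd = float(np.std(flat, ddof=1)) if flat.size > 1 else 1.0

    for j, sample in enumerate(matrix.sample_ids):
        col = vals[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if params.scope == "global" or obs.size < 2:
            if params.scope == "per_sample" and obs.size < 2:
                logger.warning(
                    "sample %r has <2 observed values; using global moments", sample
                )
            m, s = g_mean, g_sd
        else:
            m, s = float(obs.mean()), float(obs.std(ddof=1))
        col[miss] = rng.normal(m - params.downshift * s, params.width * s, size=miss.sum())
    logger.info("imputed %d missing cells", int(matrix.values.isna().to_numpy().sum()))
    out = matrix.with_values(
        pd.DataFrame(vals, index=matrix.protein_ids, columns=matrix.sample_ids)
    )
    out.scale_tag = "log2-imputed"
    return out


def zscore_within_sample(matrix: ProteinMatrix) -> ProteinMatrix:
    """Standardize each sample column to mean 0, SD 1 (sample SD, n-1).

    Used to harmonize datasets measured on different quantification scales
    before cross-dataset classification.  Requires a complete matrix (impute
    first) unless the log2 matrix happens to have no missing values.
    """
    if matrix.scale_tag == "log2" and matrix.has_missing():
        raise ValueError("z-scoring a matrix with missing values: impute first")
    if matrix.scale_tag not in ("log2", "log2-imputed"):
        raise ValueError(
            f"z-scoring expects scale_tag 'log2' or 'log2-imputed', got {matrix.scale_tag!r}"
        )
    vals = matrix.values
    sd = vals.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance sample column(s): {list(zero.index)[:5]}")
    out = matrix.with_values((vals - vals.mean(axis=0)) / sd)
    out.scale_tag = "zscored"
    return out


def _strip_isoform(ids: pd.Index) -> pd.Index:
    """Perseus-style multi-id strings keep only the part before the first ';'."""
    return pd.Index([s.split(";")[0] for s in ids])


def intersect_features(
    a: ProteinMatrix, b: ProteinMatrix
) -> tuple[ProteinMatrix, ProteinMatrix]:
    """Restrict both matrices to shared gene symbols, in sorted order.

    Matching is exact and case-sensitive; if both sides carry Perseus-style
    ``;``-separated multi-id strings, only the leading id is compared.
    """
    a_ids, b_ids = a.protein_ids, b.protein_ids
    both_multi = any(";" in s for s in a_ids) and any(";" in s for s in b_ids)
    a_key = _strip_isoform(a_ids) if both_multi else a_ids
    b_key = _strip_isoform(b_ids) if both_multi else b_ids

    shared = sorted(set(a_key) & set(b_key))
    if not shared:
        raise ValueError("no shared protein ids between matrices")

    def pick(matrix: ProteinMatrix, key: pd.Index) -> ProteinMatrix:
        lookup = {}
        for orig, k in zip(matrix.protein_ids, key):
            lookup.setdefault(k, orig)
        out = matrix.subset_proteins([lookup[k] for k in shared])
        out.values.index = pd.Index(shared, name=matrix.values.index.name)
        return out

    if both_multi:
        return pick(a, a_key), pick(b, b_key)
    return a.subset_proteins(shared), b.subset_proteins(shared)


def preprocess_pipeline(
    matrix: ProteinMatrix,
    group_of_sample: pd.Series | dict,
    min_frac: float = 0.6,
    imputation: ImputationParams | None = None,
    zscore: bool = True,
) -> ProteinMatrix:
    """Filter -> (log2 if raw) -> impute -> optionally z-score, in order."""
    out = filter_by_group_presence(matrix, group_of_sample, min_frac)
    if out.scale_tag == "raw":
        out = log2_transform(out)
    if out.has_missing():
        out = impute_downshifted_gaussian(out, imputation)
    else:
        out.scale_tag = "log2-imputed" if out.scale_tag == "log2" else out.scale_tag
    if zscore:
        out = zscore_within_sample(out)
    return out
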