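"""Canonical niche and subtype label sets.

Glioblastoma's five hallmark histomorphologic niches, in the fixed canonical
order used everywhere in this package (tie-breaks, table columns, class order):

* **LE** — leading edge, the outermost boundary of the tumor (near-normal brain)
* **IT** — infiltrating tumor, the zone between leading edge and cellular tumor
* **CT** — cellular tumor, the dense tumor core
* **MVP** — microvascular proliferation
* **PAN** — pseudopalisading cells around necrosis
"""

from __future__ import annotations

NICHES: tuple[str, ...] = ("LE", "IT", "CT", "MVP", "PAN")
"""Canonical niche order: LE < IT < CT < MVP < PAN."""

NICHE_INDEX: dict[str, int] = {n: i for i, n in enumerate(NICHES)}

SUBTYPES: tuple[str, ...] = (
    "proneural",
    "classical",
    "mesenchymal",
    "IDH-mutant",
    "normal",
)
"""Bulk-cohort transcriptional subtype labels (plus IDH-mutant and normal-brain
control groups as used in proteogenomic GBM cohorts)."""


def validate_niche(label: str) -> str:
    if label not in NICHE_INDEX:
        raise ValueError(f"unknown niche label {label!r}; expected one of {NICHES}")
    return label
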