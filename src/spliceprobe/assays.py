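"""Closed-form assay computations: qPCR abundance, ddCt folds, SPR binding.

* Ct values convert to relative template abundance as ``E ** (-Ct)`` where
  ``E`` is the actual per-cycle amplification efficiency (2 at perfect
  doubling); target abundances are normalized to a reference gene (GAPDH)
  and to vehicle (DMSO) controls to give fold changes.
* Pulldown qPCR enrichment of an active over an inactive bait uses the
  classic ``2^-ddCt`` form.
* SPR signals are normalized to the theoretical maximal response
  ``Rmax = immobilized * (analyte MW / ligand MW) * stoichiometry`` and
  expressed as percent binding (100% = full occupancy of one site).

All operations are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class QpcrRecord:
    """One Ct measurement with its per-cycle amplification efficiency."""

    sample_id: str
    target: str
    ct: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("Ct must be positive")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must lie in (1, 2]")


@dataclass(frozen=True)
class SprMeasurement:
    """SPR response with surface and mass context for normalization."""

    signal: float
    analyte_mw: float
    ligand_mw: float
    immobilized: float
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        for name in ("analyte_mw", "ligand_mw", "immobilized", "stoichiometry"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def abundance_from_ct(record: QpcrRecord) -> float:
    """Relative template abundance ``E ** (-Ct)``."""
    return record.efficiency ** (-record.ct)


def qpcr_fold_change(
    table: pd.DataFrame,
    target: str,
    reference_target: str = "GAPDH",
    control_condition: str = "DMSO",
) -> pd.DataFrame:
    """Per-sample fold change of a target vs. reference gene and controls.

    ``table`` columns: sample_id, condition, target, ct and optionally
    efficiency (default 2).  Each sample's target abundance is divided by
    its reference-gene abundance; the normalized values are then divided by
    the mean of the control-condition samples, so controls average to fold
    change 1.
    """
    df = table.copy()
    if "efficiency" not in df.columns:
        df["efficiency"] = 2.0
    df["abundance"] = [
        abundance_from_ct(QpcrRecord(str(r.sample_id), str(r.target), float(r.ct), float(r.efficiency)))
        for r in df.itertuples()
    ]
    wide = df.pivot_table(
        index=["sample_id", "condition"], columns="target", values="abundance"
    )
    for needed in (target, reference_target):
        if needed not in wide.columns:
            raise ValueError(f"target {needed!r} absent from table")
    norm = (wide[target] / wide[reference_target]).rename("normalized")
    out = norm.reset_index()
    control = out.loc[out["condition"] == control_condition, "normalized"]
    if control.empty:
        raise ValueError(f"no samples with control condition {control_condition!r}")
    out["fold_change"] = out["normalized"] / control.mean()
    return out


def ddct_fold(
    ct_target_a: float, ct_ref_a: float, ct_target_b: float, ct_ref_b: float
) -> float:
    """Fold enrichment of condition a over b by the 2^-ddCt method."""
    ddct = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return 2.0 ** (-ddct)


def spr_percent_binding(m: SprMeasurement) -> float:
    """Percent of the theoretical maximal response Rmax."""
    rmax = m.immobilized * (m.analyte_mw / m.ligand_mw) * m.stoichiometry
    if rmax == 0:
        raise ValueError("Rmax is zero")
    return 100.0 * m.signal / rmax
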