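"""Virtual-screening triage filters.

After database screening and docking, candidates are triaged by two strict
cutoffs — estimated IC50 below a potency threshold (the source study used
2 nM) and docking interaction energy above a reference value obtained by
redocking a known inhibitor (37.786 kcal/mol there) — plus top-k reporting.
The reference energy is an input, not a constant: it comes from an external
docking run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import ScreeningRecord

__all__ = ["FilterSpec", "filter_screening", "top_k"]


@dataclass(frozen=True)
class FilterSpec:
    """Triage criteria; each set criterion is applied with strict inequality.

    ``max_est_ic50_nM``: keep records with estimated IC50 strictly below this.
    ``min_energy_kcal_mol``: keep records with interaction energy strictly
    above this. At least one criterion must be set.
    """

    max_est_ic50_nM: float | None = None
    min_energy_kcal_mol: float | None = None

    def __post_init__(self) -> None:
        if self.max_est_ic50_nM is None and self.min_energy_kcal_mol is None:
            raise ValueError("at least one filter criterion must be set")
        if self.max_est_ic50_nM is not None and not self.max_est_ic50_nM > 0:
            raise ValueError("max_est_ic50_nM must be positive")

    def passes(self, record: ScreeningRecord) -> bool:
        if self.max_est_ic50_nM is not None and not record.est_ic50_nM < self.max_est_ic50_nM:
            return False
        if self.min_energy_kcal_mol is not None and not record.energy_kcal_mol > self.min_energy_kcal_mol:
            return False
        return True


def filter_screening(
    records: Sequence[ScreeningRecord], spec: FilterSpec
) -> list[ScreeningRecord]:
    """Keep records satisfying every set criterion; input order preserved."""
    return [r for r in records if spec.passes(r)]


def top_k(
    records: Sequence[ScreeningRecord], k: int, key: str = "energy"
) -> list[ScreeningRecord]:
    """The k best records by docking energy (descending) or IC50 (ascending).

    Ties are broken by compound id; ``k`` larger than the input returns the
    whole (sorted) list; ``k = 0`` returns an empty list.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if key == "energy":
        ranked = sorted(records, key=lambda r: (-r.energy_kcal_mol, r.id))
    elif key == "est_ic50":
        ranked = sorted(records, key=lambda r: (r.est_ic50_nM, r.id))
    else:
        raise ValueError(f"unknown key {key!r}; use 'energy' or 'est_ic50'")
    return ranked[:k]
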