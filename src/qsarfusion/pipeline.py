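"""End-to-end pipeline runner and report/export helpers.

Stages, in order: training/testing split validation -> per-system correlation
-> performance-based system selection -> pairwise diversity profiles ->
combination leaderboard -> screening filters (when a screening table is
given). All outputs are CSV plus a plain-text run log that records every
parameter and input checksum, so a run is reconstructible from its log.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .evaluate import evaluate_system, validate_training_split
from .fusion import CombinatorialFusion, DiversityProfile, select_systems
from .io import (
    FIXTURE_CHECKSUMS,
    fixture_path,
    load_activity_table,
    load_fixture,
    load_score_tables,
    load_screening_table,
)
from .screening import FilterSpec, filter_screening, top_k

__all__ = ["PipelineConfig", "run_pipeline", "export_divgraph", "load_divgraph"]


class PipelineConfig(BaseModel):
    """Configuration of a full pipeline run.

    Table inputs are either packaged fixture names (``table1``/``table2``/
    ``table3``) or CSV paths; for paths the system columns must be listed.
    ``scale`` and ``rule`` are logged prominently because they are the two
    conventions that change every number downstream.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    train_table: Optional[str] = "table1"
    test_table: str = "table2"
    screening_table: Optional[str] = "table3"
    train_systems: Sequence[str] = ()  # column names; ignored for fixtures
    test_systems: Sequence[str] = ()
    scale: str = "log10"
    rule: str = "mean_log"
    drop_fraction: float = 0.5  # applied to the training-stage systems
    fusion_drop_fraction: Optional[float] = None  # applied before enumeration
    max_est_ic50_nM: Optional[float] = None
    min_energy_kcal_mol: Optional[float] = 37.786
    top_n_report: int = 2
    out_dir: Path = Path("qsarfusion_out")
    verbosity: int = 1

    @model_validator(mode="after")
    def _check(self):
        if self.scale not in ("log10", "raw"):
            raise ValueError(f"scale: unknown value {self.scale!r}")
        if self.rule not in ("mean_log", "mean_raw"):
            raise ValueError(f"rule: unknown value {self.rule!r}")
        for attr in ("train_table", "test_table", "screening_table"):
            ref = getattr(self, attr)
            if ref is None:
                continue
            if ref not in FIXTURE_CHECKSUMS and not Path(ref).exists():
                raise ValueError(f"{attr}: {ref!r} is neither a fixture nor an existing path")
            if ref not in FIXTURE_CHECKSUMS and attr != "screening_table":
                cols = getattr(self, attr.replace("_table", "_systems"))
                if not cols:
                    raise ValueError(f"{attr}: system columns required for CSV path {ref!r}")
        return self


def _load_scored(ref: str, system_cols: Sequence[str]):
    if ref in FIXTURE_CHECKSUMS:
        return load_fixture(ref)
    table = load_activity_table(ref)
    return table, load_score_tables(ref, list(system_cols))


def _checksum(ref: str) -> str:
    path = fixture_path(ref) if ref in FIXTURE_CHECKSUMS else Path(ref)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_divgraph(profile: DiversityProfile, path: str | Path) -> Path:
    """Write a diversity rank/score graph as a two-column CSV (rank, score)."""
    path = Path(path)
    profile.to_frame().to_csv(path, index=False)
    return path


def load_divgraph(path: str | Path) -> pd.DataFrame:
    """Read back a rank/score graph written by :func:`export_divgraph`."""
    frame = pd.read_csv(path)
    if list(frame.columns) != ["rank", "score"]:
        raise ValueError(f"{path} is not a rank/score graph export")
    return frame


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write CSV reports plus a run log.

    Returns the report bundle as a dict of in-memory objects (split report,
    performances, fusion results, screening survivors, output paths).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"qsarfusion pipeline run", f"scale = {config.scale}", f"rule = {config.rule}"]
    for attr in ("train_table", "test_table", "screening_table"):
        ref = getattr(config, attr)
        if ref is not None:
            log_lines.append(f"{attr} = {ref} (sha256 {_checksum(ref)})")
    log_lines += [
        f"drop_fraction = {config.drop_fraction}",
        f"fusion_drop_fraction = {config.fusion_drop_fraction}",
        f"max_est_ic50_nM = {config.max_est_ic50_nM}",
        f"min_energy_kcal_mol = {config.min_energy_kcal_mol}",
    ]
    bundle: dict = {"out_dir": out}

    test_table, test_sys = _load_scored(config.test_table, config.test_systems)

    # --- stage 1: split validation + training-stage evaluation/selection
    if config.train_table is not None:
        train_table, train_sys = _load_scored(config.train_table, config.train_systems)
        split = validate_training_split(train_table, test_table)
        bundle["split_report"] = split
        pd.DataFrame([{"rule": k, "passed": v} for k, v in split.rule_flags.items()]).to_csv(
            out / "split_report.csv", index=False
        )
        log_lines.append(
            f"split: n_train={split.n_train} span_orders={split.span_orders:.3f} "
            f"flags={split.rule_flags}"
        )
        train_perfs = [evaluate_system(s, train_table, scale=config.scale) for s in train_sys]
        kept = select_systems(train_perfs, config.drop_fraction)
        bundle["train_performances"] = train_perfs
        bundle["train_selected"] = kept
        pd.DataFrame(
            [
                {"system": p.label, "n": p.n, "r_train": p.r, "selected": p.label in kept}
                for p in train_perfs
            ]
        ).to_csv(out / "train_systems.csv", index=False)
        log_lines.append(f"training-stage selection kept: {kept}")

    # --- stages 2-4: per-system r_test, diversity, leaderboard
    model = CombinatorialFusion(test_table, test_sys, scale=config.scale, rule=config.rule)
    results = model.fit(drop_fraction=config.fusion_drop_fraction)
    bundle["fusion"] = results
    pd.DataFrame(
        [{"system": p.label, "n": p.n, "r_test": p.r} for p in results.performances]
    ).to_csv(out / "test_systems.csv", index=False)
    results.leaderboard_frame().to_csv(out / "leaderboard.csv", index=False)
    results.diversity_frame().to_csv(out / "diversity.csv", index=False)
    graph_dir = out / "divgraphs"
    graph_dir.mkdir(exist_ok=True)
    for profile in results.profiles:
        export_divgraph(profile, graph_dir / f"{profile.pair[0]}+{profile.pair[1]}.csv")
    best = results.best
    log_lines.append(
        f"best combination: {best.combination.label} r_test={best.r_test:.3f} "
        f"({len(results.entries)} combinations, {len(results.profiles)} profiles)"
    )

    # --- stage 5: screening filters
    if config.screening_table is not None:
        if config.screening_table in FIXTURE_CHECKSUMS:
            records = load_fixture(config.screening_table)
        else:
            records = load_screening_table(config.screening_table)
        spec = FilterSpec(
            max_est_ic50_nM=config.max_est_ic50_nM,
            min_energy_kcal_mol=config.min_energy_kcal_mol,
        )
        survivors = filter_screening(records, spec)
        leaders = top_k(survivors, config.top_n_report, key="energy")
        bundle["screening_survivors"] = survivors
        bundle["screening_top"] = leaders
        pd.DataFrame(
            [
                {"id": r.id, "est_ic50_nM": r.est_ic50_nM, "energy_kcal_mol": r.energy_kcal_mol}
                for r in survivors
            ]
        ).to_csv(out / "screening_pass.csv", index=False)
        log_lines.append(
            f"screening: {len(records)} in, {len(survivors)} pass; "
            f"top {config.top_n_report} by energy: "
            + ", ".join(f"{r.id} ({r.energy_kcal_mol})" for r in leaders)
        )

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    if config.verbosity:
        print("\n".join(log_lines))
    return bundle
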