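"""Monte-Carlo harness: run the scenario x sample-size x censoring x method
grid, aggregate rejection rates with exact Clopper-Pearson intervals, and
emit result tables.

Each grid cell simulates ``n_reps`` trials and applies the selected tests;
a rejection is a p-value strictly below ``alpha`` (failed fits count as
non-rejections and are tallied separately so calibration distortions stay
visible).  Per-replicate seeds are spawned deterministically from the master
seed, so results are byte-identical across runs and independent of the
number of parallel workers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .lplb import LplbConfig, lplb_test
from .mfpi import mfpi_fp1_flex3_test, mfpi_fp2_flex1_test
from .scenarios import SimulationConfig, simulate_trial
from .split_tests import (
    cox_linear_interaction_test,
    median_split_test,
    optimal_split_test,
    quartile_split_test,
)
from .stepp import SteppConfig, stepp_test

__all__ = [
    "METHOD_REGISTRY",
    "StudyConfig",
    "StudyResult",
    "clopper_pearson",
    "run_study",
    "report",
]


def _stepp(data, seed=None, n_perm=500, n_boot=500):
    return stepp_test(data, SteppConfig(n_perm=n_perm, seed=seed))


def _lplb(data, seed=None, n_perm=500, n_boot=500):
    return lplb_test(data, LplbConfig(n_boot=n_boot, seed=seed))


def _plain(fn) -> Callable:
    def run(data, seed=None, n_perm=500, n_boot=500):
        return fn(data)

    return run


METHOD_REGISTRY: dict[str, Callable] = {
    "median": _plain(median_split_test),
    "quartile": _plain(quartile_split_test),
    "optimal": _plain(optimal_split_test),
    "coxlin": _plain(cox_linear_interaction_test),
    "stepp": _stepp,
    "mfpi-fp2-flex1": _plain(mfpi_fp2_flex1_test),
    "mfpi-fp1-flex3": _plain(mfpi_fp1_flex3_test),
    "lplb": _lplb,
}

_RESAMPLING_METHODS = {"stepp", "lplb"}


@dataclass(frozen=True)
class StudyConfig:
    """Simulation grid and evaluation settings for one study run."""

    scenarios: Sequence[int] = (1, 2, 3, 4, 5, 6)
    sample_sizes: Sequence[int] = (250, 500, 1000)
    cens_rates: Sequence[float] = (0.3, 2.0)
    methods: Sequence[str] = tuple(METHOD_REGISTRY)
    n_reps: int = 1000
    alpha: float = 0.05
    master_seed: int = 0
    n_perm: int = 500
    n_boot: int = 500
    workers: int = 1

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = [m for m in self.methods if m not in METHOD_REGISTRY]
        if unknown:
            raise ValueError(
                f"unknown method(s) {unknown}; registered: {sorted(METHOD_REGISTRY)}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})


@dataclass(frozen=True)
class StudyResult:
    """Aggregated rejection rates, one row per (cell, method)."""

    table: pd.DataFrame
    pvalues: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def clopper_pearson(k: int, m: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    if not (0 <= k <= m) or m < 1:
        raise ValueError("need 0 <= k <= m with m >= 1")
    a = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, m - k + 1))
    high = 1.0 if k == m else float(stats.beta.ppf(1 - a / 2, k + 1, m - k))
    return low, high


def _run_replicate(scenario, n, cens_rate, methods, rep_seed, n_perm, n_boot, alpha):
    ss = np.random.SeedSequence(rep_seed)
    data_seed, method_seed = ss.spawn(2)
    data = simulate_trial(
        SimulationConfig(scenario_id=scenario, n=n, cens_rate=cens_rate, seed=data_seed)
    )
    out = {}
    method_children = {m: s for m, s in zip(methods, method_seed.spawn(len(methods)))}
    for m in methods:
        try:
            res = METHOD_REGISTRY[m](
                data, seed=method_children[m], n_perm=n_perm, n_boot=n_boot
            )
            out[m] = (res.p_value, res.failed)
        except ValueError:
            out[m] = (1.0, True)
    return out


def _cell_seeds(master_seed: int, scenario: int, n: int, cens_idx: int, n_reps: int):
    """Per-replicate integer seeds, reproducible and unique per grid cell."""
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(scenario, n, cens_idx)
    )
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n_reps)]


def run_study(config: StudyConfig, out_dir=None, progress: bool = False) -> StudyResult:
    """Execute the full grid; returns (and optionally writes) the results.

    With ``out_dir`` set, per-cell results are written incrementally as
    ``cell_s{scenario}_n{n}_c{rate}.json`` and existing files are reused, so
    an interrupted run resumes where it stopped.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    rows = []
    pval_rows = []
    for scenario in config.scenarios:
        for n in config.sample_sizes:
            for ci, cens in enumerate(config.cens_rates):
                cell_file = (
                    out_path / f"cell_s{scenario}_n{n}_c{cens:g}.json"
                    if out_path is not None
                    else None
                )
                if cell_file is not None and cell_file.exists():
                    cell = json.loads(cell_file.read_text())
                else:
                    cell = _run_cell(config, scenario, n, ci, cens)
                    if cell_file is not None:
                        cell_file.write_text(json.dumps(cell))
                if progress:  # pragma: no cover - logging only
                    print(f"cell scenario={scenario} n={n} cens={cens} done")
                for m in config.methods:
                    pvals = np.asarray(cell["pvalues"][m])
                    failures = int(cell["failures"][m])
                    k = int((pvals < config.alpha).sum())  # p == alpha: no rejection
                    mreps = pvals.size
                    low, high = clopper_pearson(k, mreps)
                    rows.append(
                        {
                            "scenario": scenario,
                            "n": n,
                            "cens_rate": cens,
                            "method": m,
                            "k": k,
                            "m": mreps,
                            "rate": k / mreps,
                            "ci_low": low,
                            "ci_high": high,
                            "failures": failures,
                        }
                    )
                    for rep, p in enumerate(pvals):
                        pval_rows.append(
                            {
                                "scenario": scenario,
                                "n": n,
                                "cens_rate": cens,
                                "method": m,
                                "rep": rep,
                                "p_value": float(p),
                            }
                        )
    table = pd.DataFrame(rows)
    pvalues = pd.DataFrame(pval_rows)
    if out_path is not None:
        table.to_csv(out_path / "results.csv", index=False)
        pvalues.to_csv(out_path / "pvalues.csv", index=False)
    return StudyResult(table=table, pvalues=pvalues)


def _run_cell(config: StudyConfig, scenario: int, n: int, cens_idx: int, cens: float):
    seeds = _cell_seeds(config.master_seed, scenario, n, cens_idx, config.n_reps)
    args = (scenario, n, cens, tuple(config.methods))
    kw = dict(n_perm=config.n_perm, n_boot=config.n_boot, alpha=config.alpha)
    if config.workers > 1:
        results = Parallel(n_jobs=config.workers)(
            delayed(_run_replicate)(*args[:3], args[3], s, **kw) for s in seeds
        )
    else:
        results = [_run_replicate(*args[:3], args[3], s, **kw) for s in seeds]
    cell = {
        "pvalues": {m: [r[m][0] for r in results] for m in config.methods},
        "failures": {m: sum(r[m][1] for r in results) for m in config.methods},
    }
    return cell


def report(result: StudyResult, out_dir, formats: Sequence[str] = ("csv", "txt")) -> list[Path]:
    """Write the aggregated table as CSV and/or a text table grouped like the
    published layout (rows: scenario x method, columns: n x censoring)."""
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        p = out_path / "rejection_rates.csv"
        result.to_csv(p)
        written.append(p)
    if "txt" in formats:
        p = out_path / "rejection_rates.txt"
        p.write_text(render_text_table(result.table))
        written.append(p)
    return written


def render_text_table(table: pd.DataFrame) -> str:
    """Text table: one block per scenario, methods as rows, cells as
    ``rate% (low-high%)`` across n x censoring columns."""
    if table.empty:
        return "(no results)\n"
    lines = []
    col_order = sorted(
        {(n, c) for n, c in zip(table["n"], table["cens_rate"])}
    )
    header = ["method"] + [f"n={n},cens={c:g}" for n, c in col_order]
    for scenario in sorted(table["scenario"].unique()):
        sub = table[table["scenario"] == scenario]
        lines.append(f"Scenario {scenario}")
        lines.append("\t".join(header))
        for m in sub["method"].unique():
            cells = [str(m)]
            for n, c in col_order:
                row = sub[(sub["method"] == m) & (sub["n"] == n) & (sub["cens_rate"] == c)]
                if row.empty:
                    cells.append("-")
                else:
                    r = row.iloc[0]
                    cells.append(
                        f"{100 * r['rate']:.1f}% ({100 * r['ci_low']:.1f}-{100 * r['ci_high']:.1f}%)"
                    )
            lines.append("\t".join(cells))
        lines.append("")
    return "\n".join(lines)
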