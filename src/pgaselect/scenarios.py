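"""Scenario grid: low-cost feature modes × classifier families × cap sweep.

The study design crosses four fixed low-cost feature sets — all low-cost
features, only the derived low-cost deficits, none, or a set chosen by a
standard GA (recomputed per classifier) — with the four classifier families,
and sweeps the high-cost cap over a contiguous range.  Each grid cell is one
partial-GA run with a seed derived deterministically from the master seed,
so adding caps or modes never perturbs existing cells.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifiers import CLASSIFIER_KINDS, ClassifierSpec
from .data import CostPartition, FeatureSchema, FeatureTable
from .ga import GAConfig, run_pga, run_standard_ga

LOW_COST_MODES = ("all_low_cost", "low_cost_efi_only", "none", "ga_selected")

METRIC_COLUMNS = ("sensitivity", "specificity", "ppa", "npa", "accuracy", "f1")


def cell_seed(master_seed: int, *parts) -> int:
    """Stable per-cell seed below 2**31, independent of grid composition."""
    text = "|".join([str(master_seed), *[str(p) for p in parts]])
    digest = hashlib.blake2b(text.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


def resolve_fixed_set(
    mode: str,
    partition: CostPartition,
    schema: FeatureSchema,
    train_table: FeatureTable,
    spec: ClassifierSpec,
    config: GAConfig,
) -> tuple[str, ...]:
    """The fixed low-cost feature set for one scenario mode.

    ``ga_selected`` runs the standard GA over the low-cost features with the
    given classifier spec, so different classifiers generally obtain
    different sets.
    """
    if mode == "all_low_cost":
        return tuple(partition.low_cost)
    if mode == "low_cost_efi_only":
        return tuple(
            n for n in partition.low_cost if schema.features[n].source == "derived"
        )
    if mode == "none":
        return ()
    if mode == "ga_selected":
        return run_standard_ga(train_table, partition.low_cost, spec, config)
    raise ValueError(f"unknown low-cost mode {mode!r}; expected one of {LOW_COST_MODES}")


def run_grid(
    train_table: FeatureTable,
    test_table: FeatureTable,
    partition: CostPartition,
    schema: FeatureSchema,
    modes: Sequence[str] = LOW_COST_MODES,
    classifiers: Sequence[str] = CLASSIFIER_KINDS,
    caps: Sequence[int] = tuple(range(1, 33)),
    config: GAConfig = GAConfig(),
    master_seed: int = 0,
    classifier_params: Mapping[str, Mapping] | None = None,
) -> pd.DataFrame:
    """One partial-GA run per (mode, classifier, cap); long-format results.

    A failed cell is recorded with ``status="failed"`` and the error text,
    never dropped silently.  Reruns with the same master seed reproduce the
    table exactly.
    """
    n_high = len(partition.high_cost)
    bad_caps = [c for c in caps if not 1 <= c <= n_high]
    if bad_caps:
        raise ValueError(f"caps {bad_caps} outside [1, {n_high}]")
    classifier_params = classifier_params or {}
    rows = []
    for mode in modes:
        for kind in classifiers:
            spec = ClassifierSpec(
                kind=kind,
                hyperparameters=classifier_params.get(kind, {}),
                seed=cell_seed(master_seed, "clf", mode, kind),
            )
            stage1_config = replace(
                config, cap=None, seed=cell_seed(master_seed, "stage1", mode, kind)
            )
            fixed = resolve_fixed_set(mode, partition, schema, train_table, spec, stage1_config)
            for cap in caps:
                run_config = replace(config, cap=cap, seed=cell_seed(master_seed, mode, kind, cap))
                row: dict = {"mode": mode, "classifier": kind, "cap": cap}
                start = time.perf_counter()
                try:
                    result = run_pga(train_table, partition, fixed, spec, run_config, test_table)
                    row.update(result.test_metrics.as_dict())
                    row.update(
                        n_selected=len(result.selected_high_cost),
                        selected=";".join(result.selected_high_cost),
                        cv_score=result.best_cv_score,
                        status="ok",
                        error="",
                    )
                except Exception as exc:  # noqa: BLE001 - cell-level isolation
                    row.update(
                        {m: np.nan for m in METRIC_COLUMNS},
                        n_selected=0,
                        selected="",
                        cv_score=np.nan,
                        status="failed",
                        error=str(exc),
                    )
                row["runtime_s"] = time.perf_counter() - start
                rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values(["mode", "classifier", "cap"], kind="stable").reset_index(drop=True)


def render_report(
    table: pd.DataFrame,
    caps_of_interest: Sequence[int],
    out_dir=None,
) -> tuple[dict[int, pd.DataFrame], list]:
    """Comparison tables at the requested caps plus performance-vs-cap curves.

    Returns ``(tables, figure_paths)``: one table per cap with all
    (mode, classifier) metric rows at one decimal, and — when ``out_dir`` is
    given — one PNG curve per (mode, classifier) plotting five metrics
    against the cap, plus the per-cap tables as CSV.
    """
    available = sorted(table["cap"].unique().tolist())
    missing = [c for c in caps_of_interest if c not in available]
    if missing:
        raise ValueError(f"cap(s) {missing} not in results; available caps: {available}")
    tables: dict[int, pd.DataFrame] = {}
    for cap in caps_of_interest:
        sub = table[table["cap"] == cap]
        formatted = sub[["mode", "classifier", *METRIC_COLUMNS]].copy()
        formatted[list(METRIC_COLUMNS)] = formatted[list(METRIC_COLUMNS)].round(1)
        tables[cap] = formatted.reset_index(drop=True)
    figure_paths: list = []
    if out_dir is not None:
        from pathlib import Path

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cap, formatted in tables.items():
            formatted.to_csv(out_dir / f"table_cap{cap}.csv", index=False)
        curve_metrics = ("sensitivity", "specificity", "ppa", "npa", "accuracy")
        for (mode, kind), sub in table.groupby(["mode", "classifier"]):
            sub = sub.sort_values("cap")
            fig, ax = plt.subplots(figsize=(7, 4.5))
            for metric in curve_metrics:
                ax.plot(sub["cap"], sub[metric], marker=".", label=metric)
            ax.set_xlabel("high-cost feature cap")
            ax.set_ylabel("metric (%)")
            ax.set_title(f"{kind} — {mode}")
            ax.legend(fontsize=8)
            fig.tight_layout()
            path = out_dir / f"curve_{mode}_{kind}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            figure_paths.append(path)
    return tables, figure_paths
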