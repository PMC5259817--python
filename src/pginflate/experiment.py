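"""Inflation-sweep experiments and report arithmetic.

Runs the full evaluation grid: for each inflation factor ``n`` the simulated
proteogenomic search space has ``m_known`` reference peptides, ``n *
m_known`` simulated-novel peptides and ``(n + 1) * m_known`` decoy peptides
(mirroring the ``1TnD + (n+1)D`` database construction); each replicate
simulates the search and validates it with all seven methods (TD, BP, MB,
their separate-filtering variants, and the two-stage FDR), recording
accepted known/novel peptide counts, estimated FDR and — since the simulator
knows the truth — empirical FDR.

Also houses the small report arithmetic used to compare databases and
methods: percent change, decrease rate, size difference, and the overlap of
novel-peptide sets between filtering methods.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .psm_simulator import SimConfig, simulate_search, simulate_two_stage
from .validation import (
    BPConfig,
    FilterOutcome,
    assign_peps,
    boosted_rescore,
    filter_at_fdr,
    mb_filter,
    peptide_level_collapse,
    separate_filter,
    two_stage_filter,
)

logger = logging.getLogger(__name__)

ALL_METHODS = ("TD", "BP", "MB", "SepTD", "SepBP", "SepMB", "TwoStage")

TABLE_COLUMNS = [
    "n", "method", "charge", "group", "accepted_known", "accepted_novel",
    "n_decoy_at_t", "fdr_est", "fdr_emp", "threshold", "replicate", "seed",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """The inflation sweep: which n values, how many replicates, what model."""

    n_values: tuple[int, ...] = (0, 1, 2, 5)
    alpha: float = 0.01
    n_replicates: int = 20
    sim: SimConfig = field(default_factory=SimConfig)
    bp: BPConfig = field(default_factory=BPConfig)
    methods: tuple[str, ...] = ALL_METHODS
    master_seed: int = 0
    db_source: str = "synthetic"  # "synthetic" or "fasta"
    fasta_path: str | None = None

    def __post_init__(self) -> None:
        if not self.n_values or min(self.n_values) < 0:
            raise ValueError("n_values must be non-empty, all >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.db_source not in ("synthetic", "fasta"):
            raise ValueError("db_source must be 'synthetic' or 'fasta'")
        if self.db_source == "fasta" and not self.fasta_path:
            raise ValueError("db_source='fasta' requires fasta_path")


def _sub_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0] % (2**31))


def _row(outcome: FilterOutcome, n: int, charge: str, replicate: int, seed: int) -> dict:
    acc = outcome.accepted
    return {
        "n": n,
        "method": outcome.method,
        "charge": charge,
        "group": outcome.group,
        "accepted_known": int((acc["group"] == "known").sum()) if len(acc) else 0,
        "accepted_novel": int((acc["group"] == "novel").sum()) if len(acc) else 0,
        "n_decoy_at_t": outcome.n_decoy,
        "fdr_est": outcome.fdr_est,
        "fdr_emp": np.nan if outcome.fdr_emp is None else outcome.fdr_emp,
        "threshold": outcome.threshold,
        "replicate": replicate,
        "seed": seed,
    }


def run_inflation_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full sweep and return one row per (n, method, charge, group).

    Deterministic under ``config.master_seed``: every replicate/n cell
    derives its own sub-seed.
    """
    rows: list[dict] = []
    methods = set(config.methods)
    base_sim = config.sim
    if config.db_source == "fasta":
        # Search-space size (not AA length) governs random-hit competition:
        # use the unique fully-tryptic peptide count of the supplied FASTA.
        from .seqdb import DigestParams, db_stats, read_fasta

        stats = db_stats(read_fasta(config.fasta_path), DigestParams())
        base_sim = replace(base_sim, m_known=stats.n_unique_peptides)
        config = replace(config, sim=base_sim)
    for replicate in range(config.n_replicates):
        for n in config.n_values:
            seed = _sub_seed(config.master_seed, replicate, n)
            cfg = replace(
                config.sim,
                m_novel=n * config.sim.m_known,
                m_decoy=(n + 1) * config.sim.m_known,
                seed=seed,
            )
            result = simulate_search(cfg)
            if "TwoStage" in methods:
                stage1_result, provider = simulate_two_stage(cfg)
            for charge in cfg.charge_strata:
                sub = result.psms[result.psms["charge"] == charge]
                rows.extend(
                    _validate_stratum(sub, cfg, config, methods, n, charge,
                                      replicate, seed)
                )
                if "TwoStage" in methods:
                    s1 = stage1_result.psms[stage1_result.psms["charge"] == charge]
                    o1, o2 = two_stage_filter(s1, provider, config.alpha)
                    rows.append(_row(o1, n, charge, replicate, seed))
                    rows.append(_row(o2, n, charge, replicate, seed))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _validate_stratum(sub: pd.DataFrame, cfg: SimConfig, config: ExperimentConfig,
                      methods: set[str], n: int, charge: str,
                      replicate: int, seed: int) -> list[dict]:
    rows = []
    alpha = config.alpha
    # Learning steps are shared between the pooled and separate variants.
    rescored = None
    if methods & {"BP", "SepBP"}:
        rescored = boosted_rescore(sub, replace(config.bp, seed=seed))
    with_pep = None
    if methods & {"MB", "SepMB"}:
        with_pep, _fit = assign_peps(sub)
    if "TD" in methods:
        out = filter_at_fdr(peptide_level_collapse(sub, "score"), alpha, key="score")
        rows.append(_row(out, n, charge, replicate, seed))
    if "BP" in methods:
        out = filter_at_fdr(peptide_level_collapse(rescored, "rescored"), alpha,
                            key="rescored", method="BP")
        rows.append(_row(out, n, charge, replicate, seed))
    if "MB" in methods:
        out = mb_filter(with_pep, alpha, fit=_fit)
        rows.append(_row(out, n, charge, replicate, seed))
    for name, base, data in (
        ("SepTD", "TD", sub), ("SepBP", "BP", rescored), ("SepMB", "MB", with_pep)
    ):
        if name in methods:
            known, novel = separate_filter(data, alpha, method=base)  # type: ignore[arg-type]
            rows.append(_row(known, n, charge, replicate, seed))
            rows.append(_row(novel, n, charge, replicate, seed))
    return rows


# ---------------------------------------------------------------------------
# Report arithmetic
# ---------------------------------------------------------------------------


def percent_change(before: float, after: float) -> float:
    """(after - before) / before * 100, to two decimals."""
    if before <= 0:
        raise ValueError("percent_change requires a positive baseline")
    return round((after - before) / before * 100.0, 2)


def decrease_rate(count_small_n: float, count_large_n: float) -> float:
    """(small - large) / small * 100, to two decimals."""
    if count_small_n <= 0:
        raise ValueError("decrease_rate requires a positive baseline")
    return round((count_small_n - count_large_n) / count_small_n * 100.0, 2)


def size_difference(sim_total_aa: int, real_total_aa: int) -> float:
    """|real - sim| / real * 100 (denominator: the real database), two decimals."""
    if real_total_aa <= 0:
        raise ValueError("size_difference requires a positive real database size")
    return round(abs(real_total_aa - sim_total_aa) / real_total_aa * 100.0, 2)


def overlap_report(accepted_sets: Mapping[str, set]) -> dict:
    """Venn-region counts for three methods' accepted peptide sets.

    Returns each exclusive region, every pairwise intersection, the
    three-way intersection, the union size, and the proportion (percent) of
    the union identified by all three methods.
    """
    if len(accepted_sets) != 3:
        raise ValueError("overlap_report expects exactly three peptide sets")
    (ka, sa), (kb, sb), (kc, sc) = accepted_sets.items()
    sa, sb, sc = set(sa), set(sb), set(sc)
    union = sa | sb | sc
    abc = sa & sb & sc
    report = {
        f"{ka}_only": len(sa - sb - sc),
        f"{kb}_only": len(sb - sa - sc),
        f"{kc}_only": len(sc - sa - sb),
        f"{ka}&{kb}": len(sa & sb),
        f"{ka}&{kc}": len(sa & sc),
        f"{kb}&{kc}": len(sb & sc),
        f"{ka}&{kb}_only": len((sa & sb) - sc),
        f"{ka}&{kc}_only": len((sa & sc) - sb),
        f"{kb}&{kc}_only": len((sb & sc) - sa),
        "all_three": len(abc),
        "union": len(union),
        "proportion_common_pct": round(100.0 * len(abc) / len(union), 2) if union else 0.0,
    }
    return report


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD over replicates per (n, method, charge, group)."""
    g = table.groupby(["n", "method", "charge", "group"], as_index=False)
    agg = g.agg(
        accepted_known_mean=("accepted_known", "mean"),
        accepted_known_sd=("accepted_known", "std"),
        accepted_novel_mean=("accepted_novel", "mean"),
        accepted_novel_sd=("accepted_novel", "std"),
        fdr_est_mean=("fdr_est", "mean"),
        fdr_emp_mean=("fdr_emp", "mean"),
        n_replicates=("replicate", "nunique"),
    )
    return agg


def write_report(table: pd.DataFrame, outdir, config: ExperimentConfig | None = None) -> dict[str, Path]:
    """Write the results TSV, a replicate summary TSV, and a run manifest."""
    if len(table) == 0:
        raise ValueError("cannot write an empty experiment table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "results.tsv",
        "summary": outdir / "summary.tsv",
        "manifest": outdir / "manifest.json",
    }
    table.to_csv(paths["results"], sep="\t", index=False)
    summarize(table).to_csv(paths["summary"], sep="\t", index=False)
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config) if config is not None else None,
        "seeds": sorted(int(s) for s in table["seed"].unique()),
        "n_rows": int(len(table)),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
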