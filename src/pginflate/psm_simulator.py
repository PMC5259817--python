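"""Simulation of database-search results with known ground truth.

Real database searches report, per MS/MS spectrum, the best-scoring
peptide-spectrum match (PSM) out of every candidate in a concatenated
target + decoy database. This module replaces the search engine with a
generative model of those best-match scores:

* an *incorrect* match to any database partition is the maximum of ``m``
  i.i.d. per-candidate scores; with Gumbel per-candidate scores the maximum
  is again Gumbel with location shifted by ``beta * ln(m)`` — this is the
  extreme-value mechanism by which database inflation raises the score of
  random hits;
* a *correct* match (present for a fraction ``p_correct`` of spectra) draws
  its score from a Gaussian, independent of database size.

The concatenated database is partitioned into known targets (reference
proteins), novel targets (the simulated-novel inflation block) and decoys.
Each spectrum reports the argmax over its correct candidate (if any) and the
per-partition best random scores, so the provenance of every reported PSM —
and whether it is actually correct — is known exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the PSM table dialect used throughout the package.
PSM_COLUMNS = [
    "spectrum_id", "peptide_id", "score", "delta_next", "mass_error_like",
    "group", "is_decoy", "is_correct", "charge",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative model of one simulated database search.

    Defaults emulate the yeast-scale study conditions: a search space of
    688,452 unique fully-tryptic reference peptides, 20,000 spectra per
    charge stratum of which 35% have their true peptide in the database, and
    1% of true peptides lying in the novel partition. Per-candidate
    incorrect scores are standard Gumbel; correct scores are Gaussian with a
    separation placed so that an un-inflated 1% FDR cut accepts a few
    thousand peptides and five-fold inflation costs pooled target-decoy
    filtering roughly 9% of them — the sensitivity regime reported for real
    yeast searches.
    """

    n_spectra: int = 20000
    p_correct: float = 0.35
    p_novel_true: float = 0.01
    gaussian_mu: float = 23.0
    gaussian_sigma: float = 2.0
    gumbel_mu0: float = 0.0
    gumbel_beta: float = 1.0
    m_known: int = 688452
    m_novel: int = 0
    m_decoy: int = 688452
    seed: int = 0
    charge_strata: tuple[str, ...] = ("2+", "3+")
    stratum_mu_shift: Mapping[str, float] = field(
        default_factory=lambda: {"2+": 0.0, "3+": -2.0}
    )
    n_true_peptides: int = 4000
    informative_features: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.p_correct <= 1:
            raise ValueError("p_correct must be in [0, 1]")
        if not 0 <= self.p_novel_true <= 1:
            raise ValueError("p_novel_true must be in [0, 1]")
        if self.gaussian_sigma <= 0 or self.gumbel_beta <= 0:
            raise ValueError("scale parameters must be positive")
        if self.m_known < 1:
            raise ValueError("m_known must be >= 1")
        if min(self.m_novel, self.m_decoy) < 0:
            raise ValueError("partition sizes must be >= 0")
        if self.m_known + self.m_novel + self.m_decoy == 0:
            raise ValueError("at least one partition must be non-empty")
        if self.n_spectra < 1 or self.n_true_peptides < 1:
            raise ValueError("n_spectra and n_true_peptides must be >= 1")


@dataclass
class SimulatedSearchResult:
    """A simulated search: one best PSM per spectrum plus the provenance."""

    psms: pd.DataFrame
    config: SimConfig
    partition_sizes: tuple[int, int, int]  # (m_known, m_novel, m_decoy)


def max_gumbel_params(mu0: float, beta: float, m: float) -> tuple[float, float]:
    """Distribution of the maximum of ``m`` i.i.d. Gumbel(mu0, beta) draws.

    The maximum is Gumbel(mu0 + beta * ln m, beta) exactly. Non-integer
    ``m`` is permitted (it interpolates the location shift).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    return mu0 + beta * float(np.log(m)), beta


def empirical_fdr(records: pd.DataFrame) -> float:
    """Ground-truth FDR of an accepted set: incorrect targets / targets.

    Decoy records are excluded from numerator and denominator; returns 0
    when no target records are present.
    """
    targets = records[~records["is_decoy"].to_numpy(dtype=bool)]
    if len(targets) == 0:
        return 0.0
    return float((~targets["is_correct"].to_numpy(dtype=bool)).mean())


# ---------------------------------------------------------------------------
# Internal generative machinery
# ---------------------------------------------------------------------------


def _decoy_split(cfg: SimConfig) -> tuple[int, int]:
    """Split the decoy partition between the known and novel groups.

    Mirrors the construction of the matched decoy database: one reference-
    sized block pairs with the reference targets, the rest with the
    simulated-novel block. With ``m_novel = n * m_known`` and
    ``m_decoy = (n+1) * m_known`` this assigns exactly ``m_known`` decoy
    candidates to the known group and ``n * m_known`` to the novel group.
    """
    if cfg.m_decoy == 0:
        return 0, 0
    if cfg.m_novel == 0:
        return cfg.m_decoy, 0
    m_dk = int(round(cfg.m_decoy * cfg.m_known / (cfg.m_known + cfg.m_novel)))
    m_dk = min(max(m_dk, 0), cfg.m_decoy)
    return m_dk, cfg.m_decoy - m_dk


@dataclass
class _Latents:
    """Per-spectrum latent state shared between search stages."""

    spectrum_id: np.ndarray
    charge: str
    is_correct: np.ndarray  # spectrum's true peptide is in the database
    pep_idx: np.ndarray
    novel_truth: np.ndarray  # true peptide lies in the novel partition
    correct_score: np.ndarray
    correct_mass_error: np.ndarray


def _draw_latents(cfg: SimConfig, stratum: str, s_idx: int) -> _Latents:
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(s_idx, 0)))
    n = cfg.n_spectra
    is_correct = rng.random(n) < cfg.p_correct
    pep_idx = rng.integers(0, cfg.n_true_peptides, size=n)
    if cfg.m_novel > 0 and cfg.p_novel_true > 0:
        n_known_true = cfg.n_true_peptides - int(round(cfg.n_true_peptides * cfg.p_novel_true))
        n_known_true = min(max(n_known_true, 0), cfg.n_true_peptides)
    else:
        n_known_true = cfg.n_true_peptides
    novel_truth = pep_idx >= n_known_true
    mu = cfg.gaussian_mu + dict(cfg.stratum_mu_shift).get(stratum, 0.0)
    correct_score = rng.normal(mu, cfg.gaussian_sigma, size=n)
    correct_mass_error = rng.normal(0.0, 0.005, size=n)
    spectrum_id = np.array([f"{stratum}:s{i:06d}" for i in range(n)])
    return _Latents(spectrum_id, stratum, is_correct, pep_idx, novel_truth,
                    correct_score, correct_mass_error)


# Partition bookkeeping: column index -> (group, is_decoy, id prefix).
_PARTITIONS = [
    ("known", False, "RK"),   # random hit to the reference block
    ("novel", False, "RN"),   # random hit to the simulated-novel block
    ("known", True, "DK"),    # decoy paired with the reference block
    ("novel", True, "DN"),    # decoy paired with the novel block
]


def _compete(latents: _Latents, partitions: Sequence[int], cfg: SimConfig,
             rng: np.random.Generator, correct_available: np.ndarray) -> pd.DataFrame:
    """One search: argmax over the correct candidate and partition maxima."""
    n = latents.spectrum_id.size
    ncols = 1 + len(_PARTITIONS)
    scores = np.full((n, ncols), -np.inf)
    scores[correct_available, 0] = latents.correct_score[correct_available]
    rand_idx = np.zeros((len(_PARTITIONS), n), dtype=np.int64)
    for j, m in enumerate(partitions):
        # Always consume the stream in the same order for determinism.
        g = rng.gumbel(0.0, 1.0, size=n)
        idx = rng.integers(0, max(m, 1), size=n)
        if m > 0:
            mu_m, beta = max_gumbel_params(cfg.gumbel_mu0, cfg.gumbel_beta, m)
            scores[:, j + 1] = mu_m + beta * g
            rand_idx[j] = idx
    winner = np.argmax(scores, axis=1)
    top = scores[np.arange(n), winner]
    second_scores = scores.copy()
    second_scores[np.arange(n), winner] = -np.inf
    second = second_scores.max(axis=1)
    delta = np.where(np.isfinite(second), top - second, 0.0)

    group = np.empty(n, dtype=object)
    is_decoy = np.zeros(n, dtype=bool)
    is_correct = np.zeros(n, dtype=bool)
    peptide_id = np.empty(n, dtype=object)

    correct_win = winner == 0
    is_correct[correct_win] = True
    group[correct_win] = np.where(latents.novel_truth[correct_win], "novel", "known")
    pep_labels = np.array([f"PEP{i:06d}" for i in latents.pep_idx[correct_win]], dtype=object)
    peptide_id[correct_win] = pep_labels
    for j, (grp, dec, prefix) in enumerate(_PARTITIONS):
        sel = winner == j + 1
        group[sel] = grp
        is_decoy[sel] = dec
        peptide_id[sel] = np.array(
            [f"{prefix}{i:08d}" for i in rand_idx[j, sel]], dtype=object
        )

    mass_error = rng.uniform(-0.5, 0.5, size=n)
    if cfg.informative_features:
        mass_error[correct_win] = latents.correct_mass_error[correct_win]

    return pd.DataFrame(
        {
            "spectrum_id": latents.spectrum_id,
            "peptide_id": peptide_id,
            "score": top,
            "delta_next": delta,
            "mass_error_like": mass_error,
            "group": group,
            "is_decoy": is_decoy,
            "is_correct": is_correct,
            "charge": latents.charge,
        }
    )


def simulate_search(config: SimConfig) -> SimulatedSearchResult:
    """Simulate one search of all spectra against the full concatenated database.

    Per spectrum: with probability ``p_correct`` a correct candidate score is
    drawn from the Gaussian (assigned to the novel group with probability
    ``p_novel_true``); each non-empty partition contributes its best random
    Gumbel score; the reported PSM is the argmax with its true provenance.
    Fully deterministic under ``config.seed``.
    """
    frames = []
    for s_idx, stratum in enumerate(config.charge_strata):
        latents = _draw_latents(config, stratum, s_idx)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(s_idx, 1)))
        m_dk, m_dn = _decoy_split(config)
        # When m_novel == 0 the latents place every true peptide in the
        # reference, so all correct candidates are searchable.
        frames.append(
            _compete(latents, (config.m_known, config.m_novel, m_dk, m_dn),
                     config, rng, latents.is_correct)
        )
    psms = pd.concat(frames, ignore_index=True)
    return SimulatedSearchResult(
        psms=psms, config=config,
        partition_sizes=(config.m_known, config.m_novel, config.m_decoy),
    )


def simulate_two_stage(config: SimConfig) -> tuple[SimulatedSearchResult, Callable[[Sequence[str]], pd.DataFrame]]:
    """Simulate the two searches behind the two-stage FDR procedure.

    Stage 1 searches every spectrum against the reference database and its
    same-size decoy only, so correct candidates whose true peptide is novel
    are absent. The returned provider, given the spectrum identifiers left
    unidentified at stage 1, returns their best matches against the full
    proteogenomic database (fresh random-hit competition, but each
    spectrum's latent correct score is a property of the spectrum and is
    shared between stages).
    """
    stage1_frames = []
    stage2_frames = []
    for s_idx, stratum in enumerate(config.charge_strata):
        latents = _draw_latents(config, stratum, s_idx)
        rng1 = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(s_idx, 2)))
        stage1_frames.append(
            _compete(latents, (config.m_known, 0, config.m_known, 0), config,
                     rng1, latents.is_correct & ~latents.novel_truth)
        )
        rng2 = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(s_idx, 3)))
        m_dk, m_dn = _decoy_split(config)
        stage2_frames.append(
            _compete(latents, (config.m_known, config.m_novel, m_dk, m_dn),
                     config, rng2, latents.is_correct)
        )
    stage1 = pd.concat(stage1_frames, ignore_index=True)
    stage2_full = pd.concat(stage2_frames, ignore_index=True)

    def provider(residual_spectrum_ids: Sequence[str]) -> pd.DataFrame:
        wanted = set(residual_spectrum_ids)
        mask = stage2_full["spectrum_id"].isin(wanted)
        return stage2_full[mask].reset_index(drop=True)

    result = SimulatedSearchResult(
        psms=stage1, config=config,
        partition_sizes=(config.m_known, 0, config.m_known),
    )
    return result, provider


# ---------------------------------------------------------------------------
# PSM table I/O
# ---------------------------------------------------------------------------


def write_psms(psms: pd.DataFrame, path) -> None:
    """Write a PSM table as TSV with the fixed column dialect first."""
    cols = [c for c in PSM_COLUMNS if c in psms.columns]
    cols += [c for c in psms.columns if c not in cols]
    psms.to_csv(str(path), sep="\t", index=False, columns=cols)


def read_psms(path) -> pd.DataFrame:
    """Read a PSM TSV written by :func:`write_psms`."""
    return pd.read_csv(str(path), sep="\t")
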