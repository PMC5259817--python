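"""FDR filtering, EM mixture, rescoring, separate and two-stage filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gumbel_r, kendalltau, norm

from pginflate.psm_simulator import SimConfig, simulate_search, simulate_two_stage
from pginflate.validation import (
    BPConfig,
    MixtureModelFit,
    boosted_rescore,
    compute_pep,
    filter_at_fdr,
    fit_mixture_em,
    mb_fdr,
    mb_filter,
    peptide_level_collapse,
    separate_filter,
    td_fdr,
    two_stage_filter,
)

M = 688_452


def make_psms(scores, decoys, groups=None, correct=None):
    n = len(scores)
    return pd.DataFrame(
        {
            "spectrum_id": [f"s{i:05d}" for i in range(n)],
            "peptide_id": [f"p{i:05d}" for i in range(n)],
            "score": np.asarray(scores, dtype=float),
            "delta_next": np.zeros(n),
            "mass_error_like": np.zeros(n),
            "group": groups if groups is not None else ["known"] * n,
            "is_decoy": np.asarray(decoys, dtype=bool),
            "is_correct": np.asarray(correct, dtype=bool)
            if correct is not None
            else ~np.asarray(decoys, dtype=bool),
            "charge": "2+",
        }
    )


# ---------------------------------------------------------------------------
# Elementary estimators
# ---------------------------------------------------------------------------


def test_td_fdr():
    assert td_fdr(1, 100) == pytest.approx(0.01)
    assert td_fdr(0, 50) == 0.0
    assert td_fdr(5, 200) == pytest.approx(0.025)
    assert td_fdr(3, 0) == 0.0
    with pytest.raises(ValueError):
        td_fdr(-1, 10)


def test_mb_fdr():
    assert mb_fdr([0.2, 0.0]) == pytest.approx(0.1)
    assert mb_fdr([0.0] * 5) == 0.0
    assert mb_fdr([0.01] * 99 + [1.0]) == pytest.approx(0.0199)
    with pytest.raises(ValueError):
        mb_fdr([])
    with pytest.raises(ValueError):
        mb_fdr([1.5])


# ---------------------------------------------------------------------------
# Peptide-level collapse
# ---------------------------------------------------------------------------


def test_collapse_keeps_best_psm():
    df = make_psms([5.0, 7.0], [False, False])
    df["peptide_id"] = "same"
    out = peptide_level_collapse(df)
    assert len(out) == 1
    assert out["score"].iloc[0] == 7.0


def test_collapse_identity_when_distinct():
    df = make_psms([3.0, 2.0, 1.0], [False, False, False])
    out = peptide_level_collapse(df)
    assert len(out) == 3


def test_collapse_matches_brute_force(rng):
    for _ in range(100):
        n = int(rng.integers(2, 200))
        df = make_psms(rng.normal(size=n).round(1), rng.random(n) < 0.3)
        df["peptide_id"] = [f"p{i}" for i in rng.integers(0, max(2, n // 3), n)]
        got = peptide_level_collapse(df)
        # brute force: per peptide, max score; ties -> lowest spectrum_id
        expect = {}
        for r in df.itertuples():
            best = expect.get(r.peptide_id)
            if (
                best is None
                or r.score > best.score
                or (r.score == best.score and r.spectrum_id < best.spectrum_id)
            ):
                expect[r.peptide_id] = r
        assert len(got) == len(expect)
        for r in got.itertuples():
            assert expect[r.peptide_id].spectrum_id == r.spectrum_id


# ---------------------------------------------------------------------------
# Target-decoy threshold scan
# ---------------------------------------------------------------------------


def brute_force_filter(df, alpha, key="score"):
    """Accept targets at the most permissive threshold with N_D/N_T <= alpha."""
    vals = sorted(df[key].unique())
    best = None
    for t in vals:
        above = df[df[key] >= t]
        nd = int(above["is_decoy"].sum())
        nt = len(above) - nd
        if nt > 0 and nd / nt <= alpha:
            best = t
            break  # the most permissive qualifying threshold
    if best is None:
        return df.iloc[0:0]
    return df[(df[key] >= best) & ~df["is_decoy"]]


def test_filter_spec_examples():
    df = make_psms([10, 9, 8, 7, 6], [False, False, False, False, True])
    out = filter_at_fdr(df, 0.01)
    assert len(out.accepted) == 4
    assert out.n_decoy == 0

    # Alternating targets and decoys: only the lone top target survives
    # (N_D/N_T = 0/1 at the strictest threshold; every wider set fails).
    alt = make_psms([10, 9, 8, 7, 6, 5], [False, True, False, True, False, True])
    out = filter_at_fdr(alt, 0.01)
    assert len(out.accepted) == 1
    assert out.accepted["score"].iloc[0] == 10.0

    perm = filter_at_fdr(df, 0.999)
    assert len(perm.accepted) == 4


def test_filter_fdr_est_bounded_and_counts():
    df = make_psms(np.arange(100, 0, -1.0), [i % 10 == 9 for i in range(100)])
    out = filter_at_fdr(df, 0.05)
    assert out.fdr_est <= 0.05
    assert out.n_target == len(out.accepted)


def test_filter_matches_brute_force(rng):
    for trial in range(100):
        n = int(rng.integers(5, 1000))
        scores = rng.integers(0, 50, n).astype(float)  # many ties
        decoys = rng.random(n) < rng.uniform(0.1, 0.6)
        df = make_psms(scores, decoys)
        alpha = float(rng.choice([0.01, 0.05, 0.2, 0.5]))
        got = filter_at_fdr(df, alpha)
        expect = brute_force_filter(df, alpha)
        assert len(got.accepted) == len(expect)
        assert sorted(got.accepted["spectrum_id"]) == sorted(expect["spectrum_id"])


def test_filter_empty_input():
    df = make_psms([], [])
    out = filter_at_fdr(df, 0.01)
    assert out.n_target == 0 and len(out.accepted) == 0


# ---------------------------------------------------------------------------
# EM mixture model and PEP
# ---------------------------------------------------------------------------


def test_em_parameter_recovery():
    rng = np.random.default_rng(42)
    n = 20_000
    lab = rng.random(n) < 0.4
    x = np.where(lab, rng.normal(5, 1, n), rng.gumbel(0, 1, n))
    fit = fit_mixture_em(x)
    assert abs(fit.pi1 - 0.4) <= 0.03
    assert abs(fit.normal_mu - 5.0) <= 0.1
    diffs = np.diff(fit.loglik_history)
    assert (diffs >= -1e-7).all()


def test_em_null_recovery():
    rng = np.random.default_rng(7)
    fit = fit_mixture_em(rng.gumbel(0, 1, 20_000))
    assert fit.pi1 <= 0.05


def test_em_monotone_from_truth():
    rng = np.random.default_rng(3)
    n = 5_000
    lab = rng.random(n) < 0.4
    x = np.where(lab, rng.normal(5, 1, n), rng.gumbel(0, 1, n))
    truth = MixtureModelFit(pi0=0.6, gumbel_mu=0.0, gumbel_beta=1.0,
                            normal_mu=5.0, normal_sigma=1.0)
    fit = fit_mixture_em(x, init=truth, max_iter=3)
    diffs = np.diff(fit.loglik_history)
    assert (diffs >= -1e-7).all()


def test_em_requires_enough_scores():
    with pytest.raises(ValueError):
        fit_mixture_em(np.zeros(10))


def test_compute_pep_formula():
    fit = MixtureModelFit(pi0=0.7, gumbel_mu=0.0, gumbel_beta=1.0,
                          normal_mu=5.0, normal_sigma=1.0)
    s = 2.5
    f0 = gumbel_r.pdf(s, 0.0, 1.0)
    f1 = norm.pdf(s, 5.0, 1.0)
    expect = 0.7 * f0 / (0.7 * f0 + 0.3 * f1)
    assert compute_pep(fit, s) == pytest.approx(expect, rel=1e-10)
    # balance point: equal posterior mass -> 0.5
    # find s where pi0 f0 == pi1 f1 numerically
    from scipy.optimize import brentq

    bal = brentq(
        lambda t: 0.7 * gumbel_r.pdf(t, 0, 1) - 0.3 * norm.pdf(t, 5, 1), 0, 5
    )
    assert compute_pep(fit, bal) == pytest.approx(0.5, abs=1e-9)
    # past the crossover the normal dominates and PEP drops toward 0
    # (the Gumbel's exponential tail re-dominates only far beyond the data)
    assert compute_pep(fit, 6.0) < 0.05
    assert compute_pep(fit, 6.0) < compute_pep(fit, bal)
    # below the crossover the Gumbel dominates and PEP approaches 1
    assert compute_pep(fit, 1.0) > 0.95


def test_mb_filter_separation_limit():
    cfg = SimConfig(n_spectra=4000, p_correct=0.5, gaussian_mu=200.0,
                    m_known=1000, m_novel=0, m_decoy=1000, seed=1,
                    charge_strata=("2+",))
    psms = simulate_search(cfg).psms
    out = mb_filter(psms, 0.01)
    n_correct_peptides = peptide_level_collapse(psms[psms["is_correct"]])[
        "peptide_id"
    ].nunique()
    assert len(out.accepted) >= n_correct_peptides
    assert out.fdr_emp == 0.0 or out.fdr_emp < 0.01
    assert out.fdr_est <= 0.01


def test_mb_filter_pure_noise():
    hits = []
    for seed in range(10):
        cfg = SimConfig(n_spectra=5000, p_correct=0.0, m_known=M, m_novel=0,
                        m_decoy=M, seed=seed, charge_strata=("2+",))
        psms = simulate_search(cfg).psms
        out = mb_filter(psms, 0.01)
        hits.append(len(out.accepted))
    assert np.mean(hits) <= 0.01 * 5000


# ---------------------------------------------------------------------------
# Boosted rescoring
# ---------------------------------------------------------------------------


def test_boosted_rescore_deterministic():
    cfg = SimConfig(n_spectra=3000, m_novel=0, m_decoy=M, seed=11,
                    charge_strata=("2+",))
    psms = simulate_search(cfg).psms
    a = boosted_rescore(psms, BPConfig(seed=5))["rescored"]
    b = boosted_rescore(psms, BPConfig(seed=5))["rescored"]
    assert np.array_equal(a.to_numpy(), b.to_numpy())


def test_boosted_rescore_null_features_preserve_ranking():
    """With no feature signal beyond the score, rescoring ~ reranks by score."""
    taus = []
    for seed in range(5):
        cfg = SimConfig(n_spectra=8000, m_novel=0, m_decoy=M, seed=seed,
                        charge_strata=("2+",), informative_features=False)
        psms = simulate_search(cfg).psms
        r = boosted_rescore(psms, BPConfig(seed=seed))
        taus.append(kendalltau(r["score"], r["rescored"]).statistic)
    assert min(taus) > 0.9


def test_boosted_rescore_informative_feature_gains():
    """An informative mass-error feature increases 1% FDR acceptances."""
    gains = []
    for seed in range(20):
        cfg = SimConfig(n_spectra=8000, m_novel=0, m_decoy=M, seed=seed,
                        charge_strata=("2+",))
        psms = simulate_search(cfg).psms
        r = boosted_rescore(psms, BPConfig(seed=seed))
        raw = filter_at_fdr(peptide_level_collapse(psms, "score"), 0.01)
        bp = filter_at_fdr(peptide_level_collapse(r, "rescored"), 0.01, key="rescored")
        gains.append(len(bp.accepted) - len(raw.accepted))
    assert np.mean(gains) >= 0


def test_boosted_rescore_falls_back_without_decoys():
    df = make_psms([5.0, 4.0, 3.0], [False, False, False])
    out = boosted_rescore(df, BPConfig(seed=0))
    assert np.array_equal(out["rescored"], out["score"])


# ---------------------------------------------------------------------------
# Separate filtering
# ---------------------------------------------------------------------------


def test_separate_filter_novel_below_decoys():
    scores = [10, 9, 8, 3, 2, 1, 7, 6, 5]
    decoys = [False, False, False, False, False, False, True, True, True]
    groups = ["known"] * 3 + ["novel"] * 3 + ["novel"] * 3
    df = make_psms(scores, decoys, groups)
    known, novel = separate_filter(df, 0.01, method="TD")
    assert len(novel.accepted) == 0
    assert len(known.accepted) == 3


def test_separate_filter_partition_is_complete():
    cfg = SimConfig(n_spectra=4000, m_novel=2 * M, m_decoy=3 * M, seed=13,
                    charge_strata=("2+",))
    psms = simulate_search(cfg).psms
    known, novel = separate_filter(psms, 0.01, method="TD", collapse=False)
    assert set(psms["group"]) == {"known", "novel"}
    n_k = (psms["group"] == "known").sum()
    n_v = (psms["group"] == "novel").sum()
    assert n_k + n_v == len(psms)
    assert (known.accepted["group"] == "known").all()
    assert (novel.accepted["group"] == "novel").all()


def test_separate_filter_beats_pooled_on_two_population_fixture():
    """A strong known group mixed with a noisy novel group: pooled filtering
    drags the known group below threshold; separate filtering recovers it."""
    rng = np.random.default_rng(0)
    n_known, n_novel = 300, 3000
    known_t = 10 + rng.normal(0, 0.5, n_known)          # clean known targets
    known_d = rng.normal(0, 1, n_known // 3)            # weak known decoys
    novel_t = rng.normal(6, 2, n_novel)                 # noisy novel targets
    novel_d = rng.normal(6, 2, n_novel)                 # matched novel decoys
    scores = np.concatenate([known_t, known_d, novel_t, novel_d])
    decoys = np.concatenate([
        np.zeros(n_known, bool), np.ones(n_known // 3, bool),
        np.zeros(n_novel, bool), np.ones(n_novel, bool),
    ])
    groups = (["known"] * (n_known + n_known // 3)
              + ["novel"] * (2 * n_novel))
    df = make_psms(scores, decoys, groups)
    pooled = filter_at_fdr(df, 0.01)
    pooled_known = (pooled.accepted["group"] == "known").sum()
    known, _ = separate_filter(df, 0.01, method="TD", collapse=False)
    assert len(known.accepted) >= pooled_known
    assert len(known.accepted) == n_known


@pytest.mark.parametrize("method", ["BP", "MB"])
def test_separate_filter_learned_rankings(method):
    cfg = SimConfig(n_spectra=6000, m_novel=M, m_decoy=2 * M, seed=17,
                    charge_strata=("2+",))
    psms = simulate_search(cfg).psms
    known, novel = separate_filter(psms, 0.01, method=method,
                                   bp_cfg=BPConfig(seed=17))
    assert known.method == f"Sep{method}" and known.group == "known"
    assert known.fdr_est <= 0.01 and novel.fdr_est <= 0.01
    assert len(known.accepted) > 1000  # the bulk of correct PSMs survives


# ---------------------------------------------------------------------------
# Two-stage FDR
# ---------------------------------------------------------------------------


def test_two_stage_no_residual_spectra():
    df = make_psms([10, 9, 8], [False, False, False])
    called = {}

    def provider(ids):
        called["ids"] = list(ids)
        return df.iloc[0:0]

    out1, out2 = two_stage_filter(df, provider, 0.5)
    assert len(out1.accepted) == 3
    assert called["ids"] == []
    assert len(out2.accepted) == 0


def test_two_stage_accepted_never_reappear():
    cfg = SimConfig(n_spectra=6000, m_novel=2 * M, m_decoy=3 * M, seed=19,
                    charge_strata=("2+",))
    stage1, provider = simulate_two_stage(cfg)
    seen = {}

    def wrapped(ids):
        out = provider(ids)
        seen["stage2_ids"] = set(out["spectrum_id"])
        return out

    out1, out2 = two_stage_filter(stage1.psms, wrapped, 0.01)
    s1 = stage1.psms
    accepted_peps = set(out1.accepted["peptide_id"])
    accepted_spectra = set(
        s1.loc[~s1["is_decoy"] & s1["peptide_id"].isin(accepted_peps), "spectrum_id"]
    )
    assert not accepted_spectra & seen["stage2_ids"]
    assert out2.group == "stage2"


def test_two_stage_novel_comparable_to_septd():
    """Stage-2 and SepTD novel yields agree within a factor of two on average."""
    ts, sep = [], []
    for seed in range(20):
        cfg = SimConfig(n_spectra=10_000, m_novel=2 * M, m_decoy=3 * M,
                        seed=seed, charge_strata=("2+",))
        psms = simulate_search(cfg).psms
        _, novel = separate_filter(psms, 0.01, method="TD")
        sep.append(len(novel.accepted))
        stage1, provider = simulate_two_stage(cfg)
        _, out2 = two_stage_filter(stage1.psms, provider, 0.01)
        ts.append(int((out2.accepted["group"] == "novel").sum()))
    m_ts, m_sep = np.mean(ts), np.mean(sep)
    assert m_ts <= 2 * m_sep + 1
    assert m_sep <= 2 * m_ts + 1
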