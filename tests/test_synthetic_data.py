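"""Simulator ground truth: replay, rates, conversions, OMR, F2, peaks."""

import numpy as np
import pytest
from scipy import stats as sps

import convtrace as ct
from convtrace.phylo import _jc_matrix
from convtrace.synthetic_data import _site_rates


def test_zero_rates_give_identical_sequences():
    cfg = ct.SimulationConfig(
        length=300,
        region_map=ct.RegionMap([ct.Region("e1", "exon", 1, 300)]),
        rates={"exon": 0.0},
        duplication_time=3.0,
        speciation_time=1.0,
        seed=3,
    )
    truth = ct.simulate_duplicate_loci(cfg)
    seqs = {k: r.residues for k, r in truth.quartet.records.items()}
    assert len(set(seqs.values())) == 1
    assert all(not v for v in truth.mutations.values())


def test_replay_reproduces_quartet_exactly(default_truth):
    replayed = ct.replay_truth(default_truth)
    for k, rec in default_truth.quartet.records.items():
        assert replayed[k] == rec.residues


def test_replay_one_conversion_scenario():
    truth = ct.simulate_duplicate_loci(ct.default_config(seed=77, conversions="one"))
    replayed = ct.replay_truth(truth)
    for k, rec in truth.quartet.records.items():
        assert replayed[k] == rec.residues


def test_whole_locus_conversion_homogenizes_completely():
    cfg = ct.default_config(seed=5)
    cfg = ct.SimulationConfig(
        length=cfg.length,
        region_map=cfg.region_map,
        rates=cfg.rates,
        duplication_time=3.0,
        speciation_time=1.0,
        conversions=(
            ct.ConversionEvent("A", 0.0, "a", (1, 1200)),
            ct.ConversionEvent("B", 0.0, "a", (1, 1200)),
        ),
        seed=5,
    )
    truth = ct.simulate_duplicate_loci(cfg)
    for sp in ("A", "B"):
        a = truth.quartet.records[(sp, "a")].residues
        b = truth.quartet.records[(sp, "b")].residues
        assert a == b  # conversion at t=0: nothing can diverge afterwards


def test_bit_reproducibility():
    t1 = ct.simulate_duplicate_loci(ct.default_config(seed=42))
    t2 = ct.simulate_duplicate_loci(ct.default_config(seed=42))
    assert t1.ancestral == t2.ancestral
    for k in t1.quartet.records:
        assert t1.quartet.records[k].residues == t2.quartet.records[k].residues
    t3 = ct.simulate_duplicate_loci(ct.default_config(seed=43))
    assert t3.ancestral != t1.ancestral


def test_conversion_time_validation():
    cfg = ct.default_config(seed=1)
    with pytest.raises(ValueError, match="outside"):
        ct.SimulationConfig(
            length=cfg.length, region_map=cfg.region_map, rates=cfg.rates,
            duplication_time=3.0, speciation_time=1.0,
            conversions=(ct.ConversionEvent("A", 1.5, "a", (400, 900)),),
        )
    with pytest.raises(ValueError, match="tract"):
        ct.SimulationConfig(
            length=cfg.length, region_map=cfg.region_map, rates=cfg.rates,
            duplication_time=3.0, speciation_time=1.0,
            conversions=(ct.ConversionEvent("A", 0.5, "a", (400, 2000)),),
        )


def test_branch_substitution_counts_are_poisson():
    """Chi-square GOF of per-branch mutation counts against Poisson(rate x L x t)."""
    cfg_proto = ct.SimulationConfig(
        length=120,
        region_map=ct.RegionMap(
            [ct.Region("e1", "exon", 1, 60), ct.Region("i1", "intron", 61, 120)]
        ),
        rates={"exon": 0.02, "intron": 0.06},
        duplication_time=3.0,
        speciation_time=1.0,
        seed=0,
    )
    lam_pre = 2.0 * (60 * 0.02 + 60 * 0.06)  # (Td - Ts) x total site rate
    counts = []
    for s in range(1000):
        cfg = ct.SimulationConfig(
            length=cfg_proto.length, region_map=cfg_proto.region_map,
            rates=cfg_proto.rates, duplication_time=3.0, speciation_time=1.0,
            seed=50_000 + s,
        )
        truth = ct.simulate_duplicate_loci(cfg)
        counts.append(len(truth.mutations["pre:a"]))
    counts = np.array(counts)
    # bin 0..max and merge tails so every expected count is >= 5
    kmax = counts.max()
    obs = np.bincount(counts, minlength=kmax + 1).astype(float)
    exp = sps.poisson.pmf(np.arange(kmax + 1), lam_pre) * len(counts)
    exp[-1] += sps.poisson.sf(kmax, lam_pre) * len(counts)
    while exp[0] < 5:
        exp[1] += exp[0]; obs[1] += obs[0]
        exp, obs = exp[1:], obs[1:]
    while exp[-1] < 5:
        exp[-2] += exp[-1]; obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    stat, p = sps.chisquare(obs, exp * obs.sum() / exp.sum())
    assert p > 0.01


def test_shared_site_count_matches_analytic_expectation():
    """Mean within-tract paralogue-conserved count vs the JC branch-structure
    expectation, computed independently from transition matrices."""
    n_rep = 200
    cfg0 = ct.default_config(seed=0)
    ts = cfg0.speciation_time
    t_conv = {"A": 0.1, "B": 0.6}
    site_rates = _site_rates(cfg0)

    def p_ppqq(r):
        if r == 0:
            return 0.0
        d0 = r * ((ts - t_conv["A"]) + (ts - t_conv["B"]))
        m0 = _jc_matrix(d0)
        ma = _jc_matrix(r * t_conv["A"])
        mb = _jc_matrix(r * t_conv["B"])
        # P(A pair both = u | donor state x) = ma[x, u]^2; likewise for B
        pa = ma**2  # (x, u)
        pb = mb**2  # (y, w)
        total = 0.0
        for x in range(4):
            for y in range(4):
                pxy = 0.25 * m0[x, y]
                both_equal = float(pa[x].sum() * pb[y].sum())
                # subtract the u == w diagonal to keep only A-state != B-state
                same_state = float(pa[x] @ pb[y])
                total += pxy * (both_equal - same_state)
        return total

    expected = sum(p_ppqq(site_rates[pos - 1]) for pos in range(400, 901))
    observed = []
    for s in range(n_rep):
        truth = ct.simulate_duplicate_loci(ct.default_config(seed=90_000 + s))
        track = truth.track()
        n = sum(
            1
            for j, p in enumerate(track.patterns)
            if p.label == "paralogue_conserved" and 400 <= track.position(j) <= 900
        )
        observed.append(n)
    observed = np.array(observed)
    se = observed.std(ddof=1) / np.sqrt(n_rep)
    assert abs(observed.mean() - expected) <= 3 * se, (observed.mean(), expected, se)


# --- F2 counts -------------------------------------------------------------


def test_f2_counts_conserve_total():
    counts = ct.simulate_f2_counts(28, seed=3)
    assert sum(counts) == 28 and all(c >= 0 for c in counts)


def test_f2_counts_deterministic():
    assert ct.simulate_f2_counts(28, seed=9) == ct.simulate_f2_counts(28, seed=9)


def test_f2_large_n_proportions():
    n = 4_000_000
    wt, het, hom = ct.simulate_f2_counts(n, seed=1)
    assert abs(wt / n - 0.25) < 1e-3
    assert abs(het / n - 0.5) < 1e-3
    assert abs(hom / n - 0.25) < 1e-3


def test_f2_rejects_nonpositive():
    with pytest.raises(ValueError):
        ct.simulate_f2_counts(0)


# --- OMR trajectories ------------------------------------------------------


def test_omr_perfect_follower_truth_closed_form():
    cfg = ct.OMRConfig(latency=0.0, compliance=1.0, noise_sd=0.0, seed=2)
    traj, truth = ct.simulate_omr_trajectory(cfg)
    omega = cfg.schedule.angular_speed
    assert truth.delay == 0.0
    assert truth.duration == 100.0
    assert truth.distance == pytest.approx(3 * omega * 30 / 360)
    assert len(traj) == int(cfg.schedule.total_duration * cfg.frame_rate) + 1
    assert np.all(np.hypot(traj.x, traj.y) <= cfg.tank_radius + 1e-9)


def test_omr_zero_compliance_truth():
    cfg = ct.OMRConfig(latency=0.0, compliance=0.0, noise_sd=0.0, seed=2)
    _, truth = ct.simulate_omr_trajectory(cfg)
    assert truth.as_tuple() == (30.0, 0.0, 0.0)


def test_omr_latency_truth():
    cfg = ct.OMRConfig(latency=5.0, compliance=1.0, noise_sd=0.0, seed=4)
    _, truth = ct.simulate_omr_trajectory(cfg)
    assert truth.delay == 5.0
    assert truth.duration == pytest.approx(100 * 25 / 30)


def test_omr_lapses_reduce_duration():
    cfg = ct.OMRConfig(
        latency=0.0, compliance=1.0, lapse_rate=0.1, lapse_mean_duration=3.0, seed=8
    )
    _, truth = ct.simulate_omr_trajectory(cfg)
    assert truth.duration < 100.0
    assert 0 <= truth.duration


def test_omr_bad_frame_rate():
    with pytest.raises(ValueError):
        ct.OMRConfig(frame_rate=0.0)


def test_omr_deterministic():
    a, ta = ct.simulate_omr_trajectory(ct.OMRConfig(seed=5, noise_sd=0.05))
    b, tb = ct.simulate_omr_trajectory(ct.OMRConfig(seed=5, noise_sd=0.05))
    assert np.array_equal(a.x, b.x) and ta == tb


# --- peak ratios -----------------------------------------------------------


@pytest.mark.parametrize(
    "genotype,side,expected",
    [
        ("het", "upstream", (2 / 3, 1 / 3)),
        ("het", "downstream", (1 / 3, 2 / 3)),
        ("hom", "upstream", (1.0, 0.0)),
        ("hom", "downstream", (0.0, 1.0)),
        ("wt", "upstream", (0.5, 0.5)),
    ],
)
def test_peak_ratios_noise_free(genotype, side, expected):
    (ratio,) = ct.simulate_peak_ratios(genotype, [(100, side)], noise_sd=0.0)
    assert ratio == pytest.approx(expected)


def test_peak_ratios_expression_weight():
    (ratio,) = ct.simulate_peak_ratios(
        "wt", [(100, "upstream")], noise_sd=0.0, b_expression_weight=2.0
    )
    assert ratio == pytest.approx((1 / 3, 2 / 3))


def test_peak_ratios_noisy_normalized():
    ratios = ct.simulate_peak_ratios(
        "het", [(1, "upstream")] * 50, noise_sd=0.1, seed=4
    )
    for a, b in ratios:
        assert a >= 0 and b >= 0
        assert a + b == pytest.approx(1.0)
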