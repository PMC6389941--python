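"""Downstream genetic and behavioural statistics.

Covers the quantitative procedures that surround the sequence analysis
in a duplicate-gene knockout study: Mendelian segregation chi-square,
three-primer genotyping logic for a fusion allele, allele-dosage
expectations for sequencing-peak ratios, spectral-tuning-site lookup,
optomotor-response (OMR) trajectory metrics, and group comparisons
(Student's t, one-way ANOVA, Tukey HSD with compact letter display).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GenotypeCounts",
    "BandPattern",
    "OMRMetrics",
    "OMRParams",
    "RotationSchedule",
    "Trajectory",
    "TUNING_SITES",
    "segregation_chisq",
    "genotype_from_bands",
    "bands_from_genotype",
    "expected_allele_dosage",
    "tuning_site_check",
    "omr_metrics",
    "group_compare",
    "GroupComparison",
]


# ---------------------------------------------------------------------------
# Segregation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCounts:
    wt: int
    het: int
    hom: int

    def __post_init__(self) -> None:
        if min(self.wt, self.het, self.hom) < 0 or self.total < 1:
            raise ValueError("genotype counts must be non-negative with total >= 1")

    @property
    def total(self) -> int:
        return self.wt + self.het + self.hom

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.wt, self.het, self.hom)


def segregation_chisq(
    counts: GenotypeCounts | Sequence[int],
    expected_ratio: Sequence[float] = (1, 2, 1),
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of genotype counts against an expected ratio.

    Returns (chi-square statistic, degrees of freedom, p-value).  For the
    classic F2 intercross the expected ratio is 1:2:1; e.g. counts
    (8, 16, 4) against expectation (7, 14, 7) give X2 = 12/7 and
    p = 0.424.  The statistic is invariant under scaling the ratio.
    """
    obs = np.asarray(
        counts.as_tuple() if isinstance(counts, GenotypeCounts) else counts, dtype=float
    )
    ratio = np.asarray(expected_ratio, dtype=float)
    if len(ratio) != len(obs):
        raise ValueError("expected ratio length must match observed classes")
    if np.any(ratio <= 0):
        raise ValueError("expected ratio entries must be positive")
    exp = ratio / ratio.sum() * obs.sum()
    stat, p = sps.chisquare(obs, exp)
    return float(stat), len(obs) - 1, float(p)


# ---------------------------------------------------------------------------
# Three-primer genotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandPattern:
    """Gel bands from the two primer pairs of the three-primer assay.

    The fusion-specific pair amplifies only across the fused locus
    (present iff at least one fusion allele); the wild-type-specific pair
    amplifies only from the intact downstream paralogue (present iff at
    least one wild-type allele).
    """

    fusion_band_present: bool
    wildtype_b_band_present: bool


def genotype_from_bands(bands: BandPattern) -> Literal["wt", "het", "hom", "failed"]:
    """Call the genotype from the two-band pattern (``"failed"`` if no band)."""
    if bands.fusion_band_present and bands.wildtype_b_band_present:
        return "het"
    if bands.fusion_band_present:
        return "hom"
    if bands.wildtype_b_band_present:
        return "wt"
    return "failed"


def bands_from_genotype(genotype: str) -> BandPattern:
    """Band pattern implied by a genotype (inverse of :func:`genotype_from_bands`)."""
    if genotype == "wt":
        return BandPattern(False, True)
    if genotype == "het":
        return BandPattern(True, True)
    if genotype == "hom":
        return BandPattern(True, False)
    raise ValueError(f"unknown genotype {genotype!r}")


# ---------------------------------------------------------------------------
# Allele dosage and tuning sites
# ---------------------------------------------------------------------------


def expected_allele_dosage(
    genotype: Literal["wt", "het", "hom"], side: Literal["upstream", "downstream"]
) -> tuple[int, int]:
    """Copies of (a-type, b-type) sequence on one side of the fusion point.

    A fusion allele carries the a-paralogue sequence upstream of the
    fusion point and b-paralogue sequence downstream.  The wild type has
    two intact copies of each paralogue per diploid genome, so dosage is
    (2, 2) on both sides; the heterozygote carries three gene copies and
    shows 2:1 upstream and 1:2 downstream; the fusion homozygote has only
    the hybrid gene: 2:0 upstream, 0:2 downstream.
    """
    table = {
        ("wt", "upstream"): (2, 2),
        ("wt", "downstream"): (2, 2),
        ("het", "upstream"): (2, 1),
        ("het", "downstream"): (1, 2),
        ("hom", "upstream"): (2, 0),
        ("hom", "downstream"): (0, 2),
    }
    try:
        return table[(genotype, side)]
    except KeyError:
        raise ValueError(f"unknown genotype/side {(genotype, side)!r}") from None


#: The five spectral tuning sites of vertebrate long-wavelength opsins as
#: (human LWS numbering, bovine RH1 numbering) residue pairs.
TUNING_SITES: tuple[tuple[int, int], ...] = (
    (180, 164),
    (197, 181),
    (277, 261),
    (285, 269),
    (308, 292),
)


def tuning_site_check(
    index: int, numbering: Literal["human_lws", "bovine_rh1"] = "human_lws"
) -> tuple[bool, int | None]:
    """Is this residue one of the five LWS spectral tuning sites?

    Returns (is_tuning_site, paired index in the other numbering).
    """
    if index < 1:
        raise ValueError("residue index must be >= 1")
    col = 0 if numbering == "human_lws" else 1
    if numbering not in ("human_lws", "bovine_rh1"):
        raise ValueError(f"unknown numbering {numbering!r}")
    for pair in TUNING_SITES:
        if pair[col] == index:
            return True, pair[1 - col]
    return False, None


# ---------------------------------------------------------------------------
# Optomotor response metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RotationSchedule:
    """Stripe-rotation protocol: acclimation then alternating phases.

    ``phases`` is a list of (direction, duration s) with direction +1 for
    clockwise and -1 for counter-clockwise.  The standard protocol is
    30 s acclimation then clockwise / counter-clockwise / clockwise for
    30 s each.
    """

    acclimation: float = 30.0
    phases: tuple[tuple[int, float], ...] = ((1, 30.0), (-1, 30.0), (1, 30.0))
    angular_speed: float = 30.0  # stripe speed, deg/s

    @property
    def total_duration(self) -> float:
        return self.acclimation + sum(d for _, d in self.phases)

    def phase_bounds(self) -> list[tuple[float, float, int]]:
        out = []
        t = self.acclimation
        for direction, dur in self.phases:
            out.append((t, t + dur, direction))
            t += dur
        return out


@dataclass
class Trajectory:
    """Timestamped arena coordinates (seconds, tank units)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t/x/y lengths differ")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t": self.t, "x": self.x, "y": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy())


@dataclass(frozen=True)
class OMRParams:
    """Operational thresholds for OMR onset and following detection.

    The tracker emits coordinates only, so "started the OMR" needs an
    operational definition: onset fires when the cumulative
    stripe-direction angular displacement within a trailing window
    exceeds ``onset_threshold`` degrees, and is then backdated to the
    start of the contiguous same-direction run that produced the
    crossing (so a noise-free follower has zero measured delay).
    """

    onset_threshold: float = 30.0  # degrees within the window
    onset_window: float = 2.0  # seconds
    velocity_threshold: float = 5.0  # deg/s counted as "following"
    smooth_window: float = 0.5  # seconds, boxcar on angular velocity
    duration_mode: Literal["per_phase", "pooled"] = "per_phase"


@dataclass(frozen=True)
class OMRMetrics:
    delay: float  # s, in [0, phase length]
    duration: float  # percent of phase time following
    distance: float  # rounds swum with the stripes

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delay, self.duration, self.distance)


def _unwrapped_angle(traj: Trajectory, center: tuple[float, float] | None) -> np.ndarray:
    if center is None:
        center = (float(np.mean(traj.x)), float(np.mean(traj.y)))
    theta = np.arctan2(traj.y - center[1], traj.x - center[0])
    return np.degrees(np.unwrap(theta))


def omr_metrics(
    traj: Trajectory,
    schedule: RotationSchedule,
    params: OMRParams = OMRParams(),
    center: tuple[float, float] | None = None,
    tank_radius: float | None = None,
) -> OMRMetrics:
    """OMR delay / duration / distance from a coordinate trajectory.

    The trajectory is converted to an unwrapped angle about the tank
    centre (centroid of all points unless given).  Per phase, angular
    displacement is signed relative to that phase's stripe direction;
    onset follows :class:`OMRParams`; the delay of a phase with no onset
    is the full phase length; duration is the percentage of phase frames
    whose smoothed same-direction angular velocity exceeds the velocity
    threshold; distance is total positive same-direction displacement
    over all phases divided by 360.
    """
    if traj.t[-1] < schedule.total_duration - 1e-9:
        raise ValueError(
            f"trajectory ends at {traj.t[-1]:.1f}s, before the schedule "
            f"({schedule.total_duration:.1f}s)"
        )
    if tank_radius is not None:
        c = center or (float(np.mean(traj.x)), float(np.mean(traj.y)))
        r = np.hypot(traj.x - c[0], traj.y - c[1])
        if np.any(r > tank_radius * (1 + 1e-9)):
            warnings.warn("frames outside tank radius; clamping")
            scale = np.minimum(1.0, tank_radius / np.maximum(r, 1e-12))
            traj = Trajectory(traj.t, c[0] + (traj.x - c[0]) * scale, c[1] + (traj.y - c[1]) * scale)

    theta = _unwrapped_angle(traj, center)
    t = traj.t
    dt = np.diff(t)
    dtheta = np.diff(theta)
    fps = 1.0 / np.median(dt)
    win = max(1, int(round(params.smooth_window * fps)))

    def _smooth(v: np.ndarray) -> np.ndarray:
        # edge-normalized boxcar, applied within a phase so direction
        # reversals at phase boundaries do not bleed across
        kernel = np.ones(win)
        return np.convolve(v, kernel, mode="same") / np.convolve(
            np.ones_like(v), kernel, mode="same"
        )

    delays: list[float] = []
    durations: list[float] = []
    distance_deg = 0.0
    pooled_follow = pooled_frames = 0
    for start, end, direction in schedule.phase_bounds():
        mask = (t[:-1] >= start - 1e-9) & (t[:-1] < end - 1e-9)
        idx = np.where(mask)[0]
        phase_len = end - start
        if len(idx) == 0:
            delays.append(phase_len)
            durations.append(0.0)
            continue
        signed = direction * dtheta[idx]  # per-frame displacement with the stripes
        # onset: trailing-window cumulative displacement
        times = t[idx]
        window_frames = max(1, int(round(params.onset_window * fps)))
        csum = np.concatenate([[0.0], np.cumsum(np.maximum(signed, 0.0) - np.maximum(-signed, 0.0))])
        onset_frame = None
        for k in range(len(idx)):
            lo = max(0, k + 1 - window_frames)
            if csum[k + 1] - csum[lo] >= params.onset_threshold:
                onset_frame = k
                break
        if onset_frame is None:
            delays.append(phase_len)
        else:
            # backtrack to the start of the contiguous same-direction run
            j = onset_frame
            while j > 0 and signed[j - 1] > 0:
                j -= 1
            delays.append(float(times[j] - start))
        svel = _smooth(direction * dtheta[idx] / dt[idx])
        following = svel > params.velocity_threshold
        durations.append(100.0 * following.mean())
        pooled_follow += int(following.sum())
        pooled_frames += len(idx)
        distance_deg += float(np.sum(np.maximum(signed, 0.0)))

    if params.duration_mode == "pooled":
        duration = 100.0 * pooled_follow / max(pooled_frames, 1)
    else:
        duration = float(np.mean(durations))
    return OMRMetrics(
        delay=float(np.mean(delays)),
        duration=duration,
        distance=distance_deg / 360.0,
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    t_tests: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    anova_f: float | None = None
    anova_p: float | None = None
    tukey: dict[tuple[str, str], float] = field(default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False


def _compact_letter_display(
    groups: Sequence[str], significant: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are *not* significantly different.  The
    result is invariant under relabelling up to the (canonical,
    mean-independent) alphabetical processing order used here.
    """
    order = sorted(groups)
    letter_sets: list[set[str]] = [set(order)]
    for a, b in sorted(tuple(sorted(p)) for p in significant):
        split: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                split.extend([s - {a}, s - {b}])
            else:
                split.append(s)
        # absorb: drop proper subsets and duplicates
        letter_sets = []
        for s in split:
            if s and not any(s < o for o in split) and s not in letter_sets:
                letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    out = {g: "" for g in order}
    for i, s in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for g in sorted(s):
            out[g] += ch
    return out


def group_compare(
    data: dict[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Pairwise Student's t, one-way ANOVA, and Tukey HSD letters.

    ``data`` maps group label -> metric values.  t tests are two-sided
    pooled-variance, reported per pair with **no** multiple-testing
    correction (the study's explicit choice); the ANOVA is one-way across
    all groups; Tukey HSD p-values feed a compact letter display in which
    groups sharing a letter do not differ at ``alpha``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs at least 2 values")
    result = GroupComparison()
    if all(np.var(v) == 0 for v in groups.values()):
        result.degenerate = True
    labels = sorted(groups)
    for a, b in combinations(labels, 2):
        va, vb = groups[a], groups[b]
        if np.var(va) == 0 and np.var(vb) == 0 and np.mean(va) == np.mean(vb):
            result.t_tests[(a, b)] = (0.0, 1.0)
            continue
        stat, p = sps.ttest_ind(va, vb, equal_var=True)
        result.t_tests[(a, b)] = (float(stat), float(p))
    if len(labels) >= 2:
        if result.degenerate and len({float(np.mean(v)) for v in groups.values()}) == 1:
            result.anova_f, result.anova_p = 0.0, 1.0
        else:
            f, p = sps.f_oneway(*[groups[k] for k in labels])
            result.anova_f, result.anova_p = float(f), float(p)
        if result.degenerate:
            # no within-group variance anywhere: HSD is undefined; report a
            # single shared letter and leave pairwise p-values empty
            result.letters = {g: "a" for g in labels}
        else:
            res = sps.tukey_hsd(*[groups[k] for k in labels])
            significant: set[frozenset] = set()
            for i, a in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    b = labels[j]
                    pv = float(res.pvalue[i, j])
                    result.tukey[(a, b)] = pv
                    if pv < alpha:
                        significant.add(frozenset({a, b}))
            result.letters = _compact_letter_display(labels, significant)
    return result
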