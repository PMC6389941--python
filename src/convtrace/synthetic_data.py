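"""Ground-truth generators for every input the pipeline consumes.

``simulate_duplicate_loci`` evolves a tandem duplicate pair through the
history the conversion detector is built to reconstruct: an ancestral
locus duplicates at time ``Td``, the host lineage speciates at ``Ts``
(``Ts < Td``, present = 0, time in abstract substitution-clock units),
and dated non-allelic gene-conversion events overwrite a tract of one
paralogue with the other within a lineage.  Substitutions follow a
Jukes-Cantor-style Poisson process with per-region rates (introns and
intergenic sequence drift faster than exons).  Every mutation is logged,
so each run carries its own replayable truth.

The module also draws Mendelian F2 genotype counts, circular-arena
optomotor-response trajectories with a latency/compliance/lapse response
model, and sequencing electropherogram peak ratios from allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .quartet_patterns import classify_alignment, SitePatternTrack
from .seqio import (
    GAP,
    LocusQuartet,
    QuartetAlignment,
    Region,
    RegionMap,
    ROLE_ORDER,
    SequenceRecord,
)
from .study_stats import (
    OMRMetrics,
    RotationSchedule,
    Trajectory,
    expected_allele_dosage,
)

__all__ = [
    "ConversionEvent",
    "SimulationConfig",
    "Mutation",
    "SimulationTruth",
    "OMRConfig",
    "default_region_map",
    "default_config",
    "simulate_duplicate_loci",
    "replay_truth",
    "simulate_f2_counts",
    "simulate_omr_trajectory",
    "simulate_peak_ratios",
]

_BASES = np.array(list("ACGT"))

PRE_BRANCHES = ("pre:a", "pre:b")
POST_BRANCHES = tuple(f"{sp}:{par}" for sp, par in ROLE_ORDER)


@dataclass(frozen=True)
class ConversionEvent:
    """A dated non-allelic gene conversion within one lineage.

    At ``time`` (before present, must be < Ts), the ``donor`` paralogue's
    tract overwrites the other paralogue of ``species`` over the 1-based
    inclusive interval ``tract`` — perfect homogenization.
    """

    species: Literal["A", "B"]
    time: float
    donor: Literal["a", "b"]
    tract: tuple[int, int]


@dataclass(frozen=True)
class SimulationConfig:
    length: int
    region_map: RegionMap
    rates: dict[str, float]  # region kind -> substitutions/site/time-unit
    duplication_time: float  # Td
    speciation_time: float  # Ts < Td
    conversions: tuple[ConversionEvent, ...] = ()
    indel_rate: float = 0.0  # 1-bp deletions/site/unit, non-exon regions only
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.speciation_time < self.duplication_time):
            raise ValueError("need 0 < Ts < Td")
        if any(r < 0 for r in self.rates.values()) or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        for ev in self.conversions:
            if not (0 <= ev.time < self.speciation_time):
                raise ValueError(
                    f"conversion at t={ev.time} outside [0, Ts={self.speciation_time})"
                )
            if not (1 <= ev.tract[0] <= ev.tract[1] <= self.length):
                raise ValueError(f"tract {ev.tract} outside locus 1..{self.length}")


@dataclass(frozen=True)
class Mutation:
    branch: str  # e.g. "pre:a", "A:b"
    position: int  # 1-based
    time: float  # before present
    from_base: str
    to_base: str  # "-" for a deletion


@dataclass
class SimulationTruth:
    """Everything needed to verify any inference made on the simulated quartet."""

    config: SimulationConfig
    ancestral: str
    quartet: LocusQuartet
    alignment: QuartetAlignment  # positional truth alignment (columns = locus positions)
    mutations: dict[str, list[Mutation]]
    realized_conversions: tuple[ConversionEvent, ...]
    true_tracts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def track(self) -> SitePatternTrack:
        """Site-pattern track of the truth alignment."""
        return classify_alignment(self.alignment)


def default_region_map(length: int = 1200) -> RegionMap:
    """Three-exon gene body (CDS 540 bp) over positions 1-900 with an
    intergenic tail, echoing a compact tandem-duplicate locus."""
    if length < 900:
        raise ValueError("default region map needs length >= 900")
    regions = [
        Region("exon1", "exon", 1, 180),
        Region("intron1", "intron", 181, 420),
        Region("exon2", "exon", 421, 660),
        Region("intron2", "intron", 661, 780),
        Region("exon3", "exon", 781, 900),
    ]
    if length > 900:
        regions.append(Region("igs", "intergenic", 901, length))
    return RegionMap(regions)


DEFAULT_RATES = {"exon": 0.02, "intron": 0.06, "utr5": 0.06, "utr3": 0.06, "intergenic": 0.06}


def default_config(
    seed: int = 0,
    conversions: Literal["both", "one", "none"] = "both",
    tract: tuple[int, int] = (400, 900),
) -> SimulationConfig:
    """The default study preset.

    Locus 1,200 bp (gene body 1-900, see :func:`default_region_map`),
    exon rate 0.02 and intron/intergenic rate 0.06 subs/site/unit,
    duplication at Td = 3, speciation at Ts = 1.  Conversion scenarios:
    ``both`` — donor-a conversions in species A at t = 0.1 (recent) and
    species B at t = 0.6 (earlier), mirroring the asymmetric recency seen
    in the medaka sister species; ``one`` — only the species-A event;
    ``none`` — no conversion (negative control).
    """
    events: tuple[ConversionEvent, ...] = ()
    if conversions == "both":
        events = (
            ConversionEvent("A", 0.1, "a", tract),
            ConversionEvent("B", 0.6, "a", tract),
        )
    elif conversions == "one":
        events = (ConversionEvent("A", 0.1, "a", tract),)
    elif conversions != "none":
        raise ValueError(f"unknown scenario {conversions!r}")
    return SimulationConfig(
        length=1200,
        region_map=default_region_map(1200),
        rates=dict(DEFAULT_RATES),
        duplication_time=3.0,
        speciation_time=1.0,
        conversions=events,
        seed=seed,
    )


def _site_rates(cfg: SimulationConfig, indel: bool = False) -> np.ndarray:
    rates = np.zeros(cfg.length)
    for pos in range(1, cfg.length + 1):
        kind = cfg.region_map.kind_at(pos)
        if indel:
            rates[pos - 1] = cfg.indel_rate if kind not in ("exon", "unassigned") else 0.0
        else:
            rates[pos - 1] = cfg.rates.get(kind, cfg.rates.get("intergenic", 0.0))
    return rates


def _draw_events(
    rng: np.random.Generator,
    site_rates: np.ndarray,
    t_old: float,
    t_young: float,
    kind: str,
) -> list[tuple[float, int, str]]:
    """Draw (time, position, kind) Poisson events on a branch (times decrease)."""
    total = site_rates.sum() * (t_old - t_young)
    if total <= 0:
        return []
    n = rng.poisson(total)
    if n == 0:
        return []
    times = rng.uniform(t_young, t_old, size=n)
    probs = site_rates / site_rates.sum()
    positions = rng.choice(len(site_rates), size=n, p=probs) + 1
    return [(float(t), int(p), kind) for t, p in zip(times, positions)]


def _apply_substitution(
    seq: list[str], pos: int, time: float, branch: str, rng: np.random.Generator,
    log: list[Mutation],
) -> None:
    old = seq[pos - 1]
    if old == GAP:
        return  # deleted site: nothing to substitute
    choices = [b for b in "ACGT" if b != old]
    new = choices[rng.integers(0, 3)]
    seq[pos - 1] = new
    log.append(Mutation(branch, pos, time, old, new))


def simulate_duplicate_loci(cfg: SimulationConfig) -> SimulationTruth:
    """Simulate the duplication -> speciation -> conversion history.

    Fully reproducible from (config, seed).  Returns the final quartet,
    the positional truth alignment, per-branch mutation logs, and the
    realized conversion tracts.
    """
    rng = np.random.default_rng(cfg.seed)
    sub_rates = _site_rates(cfg)
    indel_rates = _site_rates(cfg, indel=True)
    ancestral = "".join(rng.choice(_BASES, size=cfg.length))
    logs: dict[str, list[Mutation]] = {b: [] for b in PRE_BRANCHES + POST_BRANCHES}

    td, ts = cfg.duplication_time, cfg.speciation_time

    # pre-speciation: each paralogue evolves independently Td -> Ts
    pre: dict[str, list[str]] = {}
    for par in ("a", "b"):
        branch = f"pre:{par}"
        seq = list(ancestral)
        events = _draw_events(rng, sub_rates, td, ts, "sub") + _draw_events(
            rng, indel_rates, td, ts, "del"
        )
        for time, pos, kind in sorted(events, key=lambda e: -e[0]):
            if kind == "sub":
                _apply_substitution(seq, pos, time, branch, rng, logs[branch])
            elif seq[pos - 1] != GAP:
                logs[branch].append(Mutation(branch, pos, time, seq[pos - 1], GAP))
                seq[pos - 1] = GAP
        pre[par] = seq

    # post-speciation: both paralogues of a species share a timeline so
    # conversions can copy the donor's current state
    final: dict[tuple[str, str], list[str]] = {}
    realized: list[ConversionEvent] = []
    tracts: dict[str, tuple[int, int]] = {}
    for species in ("A", "B"):
        seqs = {"a": list(pre["a"]), "b": list(pre["b"])}
        events: list[tuple[float, str, object]] = []
        for par in ("a", "b"):
            for time, pos, kind in _draw_events(rng, sub_rates, ts, 0.0, "sub"):
                events.append((time, par, (pos, kind)))
            for time, pos, kind in _draw_events(rng, indel_rates, ts, 0.0, "del"):
                events.append((time, par, (pos, kind)))
        for ev in cfg.conversions:
            if ev.species == species:
                events.append((ev.time, "conversion", ev))
        for time, tag, payload in sorted(events, key=lambda e: (-e[0], str(e[1]))):
            if tag == "conversion":
                ev = payload  # type: ignore[assignment]
                acceptor = "b" if ev.donor == "a" else "a"
                lo, hi = ev.tract
                seqs[acceptor][lo - 1 : hi] = seqs[ev.donor][lo - 1 : hi]
                realized.append(ev)
                tracts[species] = ev.tract
            else:
                pos, kind = payload  # type: ignore[misc]
                branch = f"{species}:{tag}"
                seq = seqs[tag]
                if kind == "sub":
                    _apply_substitution(seq, pos, time, branch, rng, logs[branch])
                elif seq[pos - 1] != GAP:
                    logs[branch].append(Mutation(branch, pos, time, seq[pos - 1], GAP))
                    seq[pos - 1] = GAP
        for par in ("a", "b"):
            final[(species, par)] = seqs[par]

    records = {
        (sp, par): SequenceRecord(
            id=f"sp{sp}_{par}", residues="".join(final[(sp, par)]),
            species=sp, paralogue=par,
        )
        for sp, par in ROLE_ORDER
    }
    quartet = LocusQuartet(
        records=records,
        region_maps={k: cfg.region_map for k in ROLE_ORDER},
    )
    cds_set = {p: i + 1 for i, p in enumerate(cfg.region_map.cds_positions())}
    alignment = QuartetAlignment(
        rows=tuple(records[k].residues for k in ROLE_ORDER),  # type: ignore[arg-type]
        cds_position=[cds_set.get(p) for p in range(1, cfg.length + 1)],
        region_kind=[cfg.region_map.kind_at(p) for p in range(1, cfg.length + 1)],
        locus_position=list(range(1, cfg.length + 1)),
    )
    return SimulationTruth(
        config=cfg,
        ancestral=ancestral,
        quartet=quartet,
        alignment=alignment,
        mutations=logs,
        realized_conversions=tuple(realized),
        true_tracts=tracts,
    )


def replay_truth(truth: SimulationTruth) -> dict[tuple[str, str], str]:
    """Rebuild the quartet from the ancestral sequence and the logs alone.

    Independent of the simulator's internal state: applies the logged
    mutations and conversion events in time order.  Byte-identical output
    to the emitted quartet is the simulator's core invariant.
    """
    cfg = truth.config
    pre: dict[str, list[str]] = {}
    for par in ("a", "b"):
        seq = list(truth.ancestral)
        for m in sorted(truth.mutations[f"pre:{par}"], key=lambda m: -m.time):
            seq[m.position - 1] = m.to_base
        pre[par] = seq
    out: dict[tuple[str, str], str] = {}
    for species in ("A", "B"):
        seqs = {"a": list(pre["a"]), "b": list(pre["b"])}
        events: list[tuple[float, int, object]] = []
        for par in ("a", "b"):
            for m in truth.mutations[f"{species}:{par}"]:
                events.append((m.time, 0, m))
        for ev in truth.realized_conversions:
            if ev.species == species:
                events.append((ev.time, 1, ev))
        for time, _, payload in sorted(events, key=lambda e: (-e[0], e[1])):
            if isinstance(payload, ConversionEvent):
                acceptor = "b" if payload.donor == "a" else "a"
                lo, hi = payload.tract
                seqs[acceptor][lo - 1 : hi] = seqs[payload.donor][lo - 1 : hi]
            else:
                seqs[payload.branch.split(":")[1]][payload.position - 1] = payload.to_base
        for par in ("a", "b"):
            out[(species, par)] = "".join(seqs[par])
    return out


# ---------------------------------------------------------------------------
# F2 genotype counts
# ---------------------------------------------------------------------------


def simulate_f2_counts(n: int, seed: int = 0) -> tuple[int, int, int]:
    """Multinomial draw of (wt, het, hom) counts from the 1:2:1 F2 expectation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    wt, het, hom = rng.multinomial(n, [0.25, 0.5, 0.25])
    return int(wt), int(het), int(hom)


# ---------------------------------------------------------------------------
# Optomotor response trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OMRConfig:
    """Generator settings for a circular-arena OMR trajectory.

    The fish orbits at a fixed fraction of the tank radius; after
    ``latency`` seconds into each rotation phase it follows the stripes
    at their angular speed — if it "complies" with that phase at all
    (per-phase Bernoulli with probability ``compliance``) — except during
    lapse episodes (Poisson arrivals, exponential durations) in which it
    ignores the stripes.  Positional noise is isotropic Gaussian.
    """

    tank_radius: float = 10.0
    schedule: RotationSchedule = RotationSchedule()
    latency: float = 1.0  # s after phase start before following begins
    compliance: float = 1.0  # per-phase probability of responding
    lapse_rate: float = 0.0  # episodes per second
    lapse_mean_duration: float = 2.0  # s
    noise_sd: float = 0.0  # tank units, per coordinate
    orbit_fraction: float = 0.7
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if not (0 <= self.compliance <= 1):
            raise ValueError("compliance must be in [0, 1]")
        if self.latency < 0 or self.lapse_rate < 0:
            raise ValueError("latency and lapse rate must be >= 0")


def simulate_omr_trajectory(cfg: OMRConfig) -> tuple[Trajectory, OMRMetrics]:
    """Generate a trajectory plus the truth metrics of the generating process.

    Truth metrics come from the latent states (compliance draws, lapse
    episodes), not from the emitted coordinates — estimator error is then
    measurable against them.
    """
    rng = np.random.default_rng(cfg.seed)
    sched = cfg.schedule
    omega = sched.angular_speed
    n_frames = int(round(sched.total_duration * cfg.frame_rate)) + 1
    t = np.arange(n_frames) / cfg.frame_rate

    complies = [bool(rng.random() < cfg.compliance) for _ in sched.phases]

    # lapse episodes over the whole test
    lapses: list[tuple[float, float]] = []
    if cfg.lapse_rate > 0:
        clock = 0.0
        while True:
            clock += rng.exponential(1.0 / cfg.lapse_rate)
            if clock >= sched.total_duration:
                break
            lapses.append((clock, clock + rng.exponential(cfg.lapse_mean_duration)))
        # merge overlaps so truth interval arithmetic stays exact
        merged: list[tuple[float, float]] = []
        for lo, hi in sorted(lapses):
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        lapses = merged

    def in_lapse(time: float) -> bool:
        return any(lo <= time < hi for lo, hi in lapses)

    bounds = sched.phase_bounds()
    theta = np.empty(n_frames)
    theta[0] = rng.uniform(0, 360)
    dt = 1.0 / cfg.frame_rate
    for i in range(1, n_frames):
        time = t[i - 1]
        vel = 0.0
        for p, (start, end, direction) in enumerate(bounds):
            if start <= time < end:
                if complies[p] and (time - start) >= cfg.latency and not in_lapse(time):
                    vel = direction * omega
                break
        theta[i] = theta[i - 1] + vel * dt

    r = cfg.orbit_fraction * cfg.tank_radius
    x = r * np.cos(np.radians(theta))
    y = r * np.sin(np.radians(theta))
    if cfg.noise_sd > 0:
        x = x + rng.normal(0, cfg.noise_sd, n_frames)
        y = y + rng.normal(0, cfg.noise_sd, n_frames)
        rad = np.hypot(x, y)
        over = rad > cfg.tank_radius
        if np.any(over):
            x[over] *= cfg.tank_radius / rad[over]
            y[over] *= cfg.tank_radius / rad[over]

    # truth metrics from the latent process
    delays, durations = [], []
    distance_deg = 0.0
    for p, (start, end, direction) in enumerate(bounds):
        phase_len = end - start
        if not complies[p]:
            delays.append(phase_len)
            durations.append(0.0)
            continue
        delays.append(min(cfg.latency, phase_len))
        lo = min(start + cfg.latency, end)
        follow_time = end - lo
        for llo, lhi in lapses:
            follow_time -= max(0.0, min(lhi, end) - max(llo, lo))
        follow_time = max(0.0, follow_time)
        durations.append(100.0 * follow_time / phase_len)
        distance_deg += follow_time * omega
    truth = OMRMetrics(
        delay=float(np.mean(delays)),
        duration=float(np.mean(durations)),
        distance=distance_deg / 360.0,
    )
    return Trajectory(t, x, y), truth


# ---------------------------------------------------------------------------
# Electropherogram peak ratios
# ---------------------------------------------------------------------------


def simulate_peak_ratios(
    genotype: Literal["wt", "het", "hom"],
    sites: Sequence[tuple[int, Literal["upstream", "downstream"]]],
    noise_sd: float = 0.0,
    seed: int = 0,
    b_expression_weight: float = 1.0,
) -> list[tuple[float, float]]:
    """Per-site (a-allele, b-allele) sequencing-peak signal fractions.

    Mean signal is proportional to allele dosage (optionally weighted by
    ``b_expression_weight`` to emulate unequal paralogue expression) plus
    truncated Gaussian noise; each site's pair is renormalized to sum
    to 1.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _pos, side in sites:
        na, nb = expected_allele_dosage(genotype, side)
        wa, wb = float(na), float(nb) * b_expression_weight
        total = wa + wb
        if total == 0:
            raise ValueError("zero total dosage")
        sa, sb = wa / total, wb / total
        if noise_sd > 0:
            sa = max(0.0, sa + rng.normal(0, noise_sd))
            sb = max(0.0, sb + rng.normal(0, noise_sd))
            s = sa + sb
            if s > 0:
                sa, sb = sa / s, sb / s
        out.append((sa, sb))
    return out
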