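"""Synthetic data generators for every pipeline stage.

Each generator emulates the statistical structure of one experimental input —
toy multi-domain Cα structures with a known ground-truth conformation,
cross-link tables with controlled true/false-positive geometry, ALEX photon
streams with static or two-state-switching FRET populations, peptide-level
HDX uptake tables, and noisy Hill binding isotherms — and is deterministic
given its seed, emitting machine-readable ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .partition import DomainPartition
from .structures import CA_VIRTUAL_BOND, Structure, StructureError, _relax_fill

__all__ = [
    "ToyGroundTruth",
    "make_toy_multidomain",
    "simulate_crosslinks",
    "AlexSpec",
    "Population",
    "StreamConfig",
    "simulate_photon_stream",
    "HdxPeptideProfile",
    "make_hdx_profiles",
    "simulate_hdx",
    "simulate_isotherm",
]


# ---------------------------------------------------------------------------
# toy multi-domain structures
# ---------------------------------------------------------------------------


@dataclass
class ToyGroundTruth:
    """A generated structure with known conformation and restraint geometry."""

    structure: Structure
    partition: DomainPartition
    transforms: list[tuple[np.ndarray, np.ndarray]]  # per-domain (R, t) vs local frame
    sites: list[int]  # designated cross-linkable residues
    conformation: str
    contact_bound: float

    def domain_centroids(self) -> dict[str, np.ndarray]:
        res, xyz = self.structure.ca_table()
        out = {}
        for label, ranges in self.partition.segments.items():
            mask = np.zeros(len(res), dtype=bool)
            for a, b in ranges:
                mask |= (res >= a) & (res <= b)
            out[label] = xyz[mask].mean(axis=0)
        return out


def _compact_walk(n: int, rng: np.random.Generator, r_max: float) -> np.ndarray:
    """Compact self-avoiding Cα walk of ``n`` beads inside a sphere of radius r_max."""
    beads = [np.zeros(3)]
    for _ in range(n - 1):
        cur = beads[-1]
        centroid = np.mean(beads, axis=0)
        placed = False
        for _try in range(300):
            d = rng.standard_normal(3) + 0.35 * (centroid - cur) / max(np.linalg.norm(centroid - cur), 1.0)
            d /= np.linalg.norm(d)
            pos = cur + CA_VIRTUAL_BOND * d
            if np.linalg.norm(pos - centroid) > r_max:
                continue
            if len(beads) > 1:
                dists = np.linalg.norm(np.asarray(beads[:-1]) - pos, axis=1)
                if dists.min() < 3.5:
                    continue
            beads.append(pos)
            placed = True
            break
        if not placed:
            raise StructureError("could not grow a compact self-avoiding walk; try another seed")
    arr = np.asarray(beads)
    return arr - arr.mean(axis=0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_toy_multidomain(
    n_domains: int = 3,
    sizes: tuple[int, ...] | None = None,
    conformation: str = "closed",
    seed: int = 0,
    contact_bound: float = 22.0,
    open_separation: float = 45.0,
    linker_length: int = 8,
    site_every: int = 4,
) -> ToyGroundTruth:
    """Generate a multi-domain Cα structure with a known conformation.

    Domains are compact self-avoiding walks placed with centroids on a regular
    polygon of side ``contact_bound`` ("closed") or ``open_separation``
    ("open"); consecutive domains are joined by relaxed Cα linkers.  Domain
    shapes depend only on the seed, so open and closed variants of one seed
    share within-domain geometry and differ by rigid transforms alone.
    Every ``site_every``-th residue of each domain is a designated
    cross-linkable site (a stand-in for surface lysines).
    """
    if n_domains < 2:
        raise ValueError("need at least 2 domains")
    sizes = tuple(sizes or (40,) * n_domains)
    if any(s < 20 for s in sizes):
        raise ValueError("domain sizes must be >= 20 residues")
    if conformation not in ("closed", "open"):
        raise ValueError(f"unknown conformation {conformation!r}")

    rng_dom = np.random.default_rng([seed, 11])
    local = [_compact_walk(s, rng_dom, r_max=3.2 * s ** (1 / 3)) for s in sizes]

    # placement and linker routing can be geometrically unlucky; retry with a
    # fresh (still seed-deterministic) placement stream
    last_err: StructureError | None = None
    for attempt in range(8):
        rng_place = np.random.default_rng(
            [seed, 13, 0 if conformation == "closed" else 1, attempt]
        )
        try:
            return _assemble_toy(
                local, conformation, contact_bound, open_separation, linker_length,
                site_every, n_domains, rng_place,
            )
        except StructureError as exc:
            last_err = exc
    raise StructureError(f"toy generation failed after retries: {last_err}")


def _assemble_toy(
    local, conformation, contact_bound, open_separation, linker_length,
    site_every, n_domains, rng_place,
) -> ToyGroundTruth:
    sep = contact_bound if conformation == "closed" else open_separation
    max_span = (linker_length + 1) * (CA_VIRTUAL_BOND - 0.2)
    placed: list[np.ndarray] = []
    transforms: list[tuple[np.ndarray, np.ndarray]] = []
    for i, dom in enumerate(local):
        if i == 0:
            center = np.zeros(3)
        elif conformation == "closed":
            # regular polygon with side length = contact bound
            if n_domains == 2:
                center = np.array([sep, 0.0, 0.0])
            else:
                rad = sep / (2.0 * math.sin(math.pi / n_domains))
                ang = 2.0 * math.pi * i / n_domains
                center = np.array([rad * math.cos(ang) - rad, rad * math.sin(ang), 0.0])
        else:
            # extended chain: next centroid along the previous exit-terminus
            # direction, so an 8-residue linker can still bridge the gap
            prev_center = transforms[i - 1][1]
            exit_pt = placed[i - 1][-1]
            u = exit_pt - prev_center
            offset = float(np.linalg.norm(u))
            u /= max(offset, 1e-9)
            # keep the next centroid within linker reach of the exit terminus
            reach = float(np.clip(sep - offset, 18.0, 26.0))
            center = exit_pt + reach * u
            # steer away from earlier domains so the chain stays extended
            for rot_prev, c_prev in transforms[:-1]:
                v = center - c_prev
                if np.linalg.norm(v) < 1.2 * sep:
                    u = u + 1.5 * v / max(np.linalg.norm(v), 1e-9)
                    u /= max(np.linalg.norm(u), 1e-9)
                    center = exit_pt + reach * u
        best_rot, best_gap = None, np.inf
        for _try in range(300):
            rot = _random_rotation(rng_place)
            coords = dom @ rot.T + center
            gap = 0.0 if i == 0 else float(np.linalg.norm(coords[0] - placed[i - 1][-1]))
            clash = any(cdist(coords, p).min() < 4.5 for p in placed)
            if clash:
                continue
            if i == 0 or (6.0 <= gap <= max_span):
                best_rot, best_gap = rot, gap
                break
            if gap < best_gap:
                best_rot, best_gap = rot, gap
        if best_rot is None:
            raise StructureError(f"could not place domain {i} without clashes; try another seed")
        if i > 0 and best_gap > max_span:
            raise StructureError(
                f"domain {i} termini {best_gap:.1f} Å apart exceed linker reach {max_span:.1f} Å"
            )
        placed.append(dom @ best_rot.T + center)
        transforms.append((best_rot, center))

    # assemble chain: domain 0, linker, domain 1, linker, ...
    resnum, xyz = [], []
    segments: dict[str, list[tuple[int, int]]] = {}
    next_res = 1
    for i, coords in enumerate(placed):
        if i > 0:
            a = np.asarray(xyz[-1])
            b = coords[0]
            existing = np.vstack([np.asarray(xyz), np.vstack(placed[i:])])
            beads = None
            best, best_clear = None, -np.inf
            for _try in range(60):
                cand = _relax_fill(a, b, linker_length, rng_place, obstacles=existing)
                steps = np.linalg.norm(np.diff(np.vstack([a, cand, b]), axis=0), axis=1)
                if np.any(np.abs(steps - CA_VIRTUAL_BOND) > 0.2):
                    continue
                clear = float(cdist(cand, existing).min())
                if clear >= 3.2:
                    beads = cand
                    break
                if clear > best_clear:
                    best, best_clear = cand, clear
            if beads is None:
                if best is None or best_clear < 3.0:
                    raise StructureError(
                        f"could not route linker {i} without clashes; try another seed"
                    )
                beads = best
            for p in beads:
                resnum.append(next_res)
                xyz.append(p)
                next_res += 1
        start = next_res
        for p in coords:
            resnum.append(next_res)
            xyz.append(p)
            next_res += 1
        segments[f"D{i + 1}"] = [(start, next_res - 1)]

    n = len(resnum)
    structure = Structure(
        chain=np.full(n, "A"),
        resnum=np.array(resnum),
        resname=np.full(n, "GLY"),
        atomname=np.full(n, "CA"),
        element=np.full(n, "C"),
        xyz=np.asarray(xyz),
    )
    partition = DomainPartition(segments)
    sites = []
    for label, ranges in segments.items():
        a, b = ranges[0]
        sites.extend(range(a, b + 1, site_every))
    return ToyGroundTruth(
        structure=structure,
        partition=partition,
        transforms=transforms,
        sites=sites,
        conformation=conformation,
        contact_bound=contact_bound,
    )


def simulate_crosslinks(
    ground_truth: ToyGroundTruth,
    n_true: int = 12,
    n_false: int = 0,
    cutoff: float = 25.0,
    seed: int = 0,
    inter_domain_only: bool = True,
    sasd_max: float | None = 35.0,
) -> tuple[str, pd.DataFrame]:
    """Sample cross-link pairs with controlled geometry against ground truth.

    True links join sites whose ground-truth Euclidean Cα-Cα distance is at
    most ``cutoff`` and (like a real surface-reactive cross-linker) whose
    solvent-accessible surface distance is within ``sasd_max``; false links
    join sites farther apart than ``cutoff + 10`` Å.  Returns (CSV text in
    the cross-link table schema, truth table with distances and labels).
    """
    rng = np.random.default_rng(seed)
    st = ground_truth.structure
    sites = ground_truth.sites
    coords = np.array([st.ca_coord(r) for r in sites])
    part = ground_truth.partition
    labels = [part.label_of(r) for r in sites]

    dist = squareform(pdist(coords))
    pairs_true, pairs_false = [], []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if inter_domain_only and labels[i] == labels[j]:
                continue
            if dist[i, j] <= cutoff:
                pairs_true.append((sites[i], sites[j], dist[i, j]))
            elif dist[i, j] > cutoff + 10.0:
                pairs_false.append((sites[i], sites[j], dist[i, j]))
    if sasd_max is not None and pairs_true:
        from .xl import SasdCalculator

        calc = SasdCalculator(st, spacing=1.5)
        sasd = calc.sasd_many([(a, b) for a, b, _ in pairs_true])
        pairs_true = [p for p, s in zip(pairs_true, sasd) if s <= sasd_max]
    if len(pairs_true) < n_true:
        raise ValueError(f"only {len(pairs_true)} site pairs below {cutoff} Å (need {n_true})")
    if len(pairs_false) < n_false:
        raise ValueError(f"only {len(pairs_false)} site pairs beyond {cutoff + 10} Å (need {n_false})")

    chosen = [
        (p, True) for p in [pairs_true[i] for i in rng.choice(len(pairs_true), n_true, replace=False)]
    ] + [
        (p, False) for p in [pairs_false[i] for i in rng.choice(len(pairs_false), n_false, replace=False)]
    ]
    rows, truth = [], []
    for k, ((ra, rb, d), is_true) in enumerate(chosen):
        rows.append(f"toy,{ra},toy,{rb},DSBU,xl{k + 1}")
        truth.append({"id": f"xl{k + 1}", "residue_a": ra, "residue_b": rb, "distance": d, "is_true": is_true})
    csv = "protein_a,residue_a,protein_b,residue_b,chemistry,id\n" + "\n".join(rows) + "\n"
    return csv, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# ALEX photon streams
# ---------------------------------------------------------------------------


@dataclass
class AlexSpec:
    """Alternating-laser-excitation timing: 40 μs period, 40/40/20 duty."""

    period_s: float = 40e-6
    donor_window: tuple[float, float] = (0.0, 0.4)  # fractions of the period
    acceptor_window: tuple[float, float] = (0.5, 0.9)

    def excitation_of(self, times_s: np.ndarray) -> np.ndarray:
        """0 = donor excitation, 1 = acceptor excitation, -1 = dark."""
        frac = (times_s % self.period_s) / self.period_s
        out = np.full(len(times_s), -1, dtype=np.int8)
        out[(frac >= self.donor_window[0]) & (frac < self.donor_window[1])] = 0
        out[(frac >= self.acceptor_window[0]) & (frac < self.acceptor_window[1])] = 1
        return out


@dataclass
class Population:
    """One molecular species: static FRET value, or two-state switching.

    ``E`` is the true FRET efficiency (for two-state species the pair
    ``(E, E2)`` with exchange rates ``k12``/``k21`` in s⁻¹), ``S`` the true
    stoichiometry (0.5 for 1:1 doubly-labelled; ~1 donor-only, ~0
    acceptor-only) and ``weight`` the species fraction.
    """

    E: float
    S: float = 0.5
    weight: float = 1.0
    E2: float | None = None
    k12: float = 0.0
    k21: float = 0.0

    @property
    def dynamic(self) -> bool:
        return self.E2 is not None


@dataclass
class StreamConfig:
    populations: list[Population] = field(default_factory=lambda: [Population(E=0.5)])
    burst_rate: float = 40.0  # bursts per second entering the confocal volume
    burst_size_mean: float = 90.0  # mean detected photons per burst
    burst_size_sigma: float = 0.45  # lognormal shape
    burst_duration_ms: float = 1.0
    background: dict = field(
        default_factory=lambda: {"dd": 350.0, "ad": 250.0, "aa": 500.0, "da": 80.0}
    )  # Hz per photon stream
    alex: AlexSpec = field(default_factory=AlexSpec)
    alpha: float = 0.0  # donor leakage applied by the forward model
    delta: float = 0.0  # direct acceptor excitation
    gamma: float = 1.0  # quantum-yield/detection normalisation
    beta: float = 1.0  # excitation normalisation
    clock_rate: float = 1e8  # Hz

    def validate(self) -> None:
        w = sum(p.weight for p in self.populations)
        if not math.isclose(w, 1.0, rel_tol=1e-6):
            raise ValueError(f"population weights sum to {w}, expected 1")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("background rates must be >= 0")


def _window_times(rng: np.random.Generator, n: int, t0: float, dur: float, alex: AlexSpec, window: int) -> np.ndarray:
    """Uniform photon times within [t0, t0+dur] restricted to one excitation window."""
    lo, hi = (alex.donor_window, alex.acceptor_window)[window]
    t = t0 + rng.uniform(0.0, dur, n)
    period_start = np.floor(t / alex.period_s) * alex.period_s
    return period_start + (lo + rng.uniform(0.0, 1.0, n) * (hi - lo)) * alex.period_s


def simulate_photon_stream(
    config: StreamConfig, duration: float = 30.0, seed: int = 0
) -> tuple[dict, pd.DataFrame]:
    """Simulate a two-detector ALEX photon stream with ground truth.

    Burst-level model (no explicit diffusion): burst arrivals are Poisson,
    sizes lognormal; per burst a species is drawn and its four-stream counts
    follow the forward model implied by its (E, S) and the configured
    correction factors (α, δ, γ, β).  Two-state species modulate the
    acceptor-routing probability of donor-excitation photons along a simulated
    Markov state trajectory.  Poisson background is added per stream.

    Returns a dict with ``timestamps`` (clock ticks), ``detectors``
    (0 donor / 1 acceptor), ``clock_rate``, ``alex`` — the photon-stream
    container the burst module reads — and a ground-truth burst table.
    """
    config.validate()
    if duration < 1.0:
        raise ValueError("duration must be >= 1 s")
    rng = np.random.default_rng(seed)
    alex = config.alex
    a, d_, g, b = config.alpha, config.delta, config.gamma, config.beta

    n_bursts = rng.poisson(config.burst_rate * duration)
    t_bursts = np.sort(rng.uniform(0.0, duration, n_bursts))
    weights = np.array([p.weight for p in config.populations])
    species = rng.choice(len(config.populations), size=n_bursts, p=weights)
    mu = math.log(config.burst_size_mean) - 0.5 * config.burst_size_sigma**2
    sizes = rng.lognormal(mu, config.burst_size_sigma, n_bursts)
    dur_b = config.burst_duration_ms * 1e-3

    times_all, chan_all = [], []
    truth_rows = []
    for k in range(n_bursts):
        pop = config.populations[species[k]]
        lam = sizes[k]  # corrected donor-excitation signal scale
        t0 = t_bursts[k]
        if pop.S <= 1e-6:  # acceptor-only species: all signal under Aex
            f_aa = lam
        else:
            f_aa = lam * (1.0 - pop.S) / pop.S
        n_aa = rng.poisson(b * f_aa)
        t_aa = _window_times(rng, n_aa, t0, dur_b, alex, 1)
        times_all.append(t_aa)
        chan_all.append(np.ones(n_aa, dtype=np.int8))

        if pop.S <= 1e-6:
            n_ad = rng.poisson(d_ * b * f_aa)  # direct excitation only
            t_ad = _window_times(rng, n_ad, t0, dur_b, alex, 0)
            times_all.append(t_ad)
            chan_all.append(np.ones(n_ad, dtype=np.int8))
            n_dex = n_ad
            e_true = np.nan
        elif not pop.dynamic:
            e = pop.E
            mean_dd = (1.0 - e) * lam / g
            mean_ad = e * lam + a * mean_dd + d_ * (b * f_aa)
            n_dd = rng.poisson(mean_dd)
            n_ad = rng.poisson(mean_ad)
            t_dd = _window_times(rng, n_dd, t0, dur_b, alex, 0)
            t_ad = _window_times(rng, n_ad, t0, dur_b, alex, 0)
            times_all.extend([t_dd, t_ad])
            chan_all.extend([np.zeros(n_dd, dtype=np.int8), np.ones(n_ad, dtype=np.int8)])
            n_dex = n_dd + n_ad
            e_true = e
        else:
            # total Dex detection rate taken at the mean of the two states;
            # routing probability follows the instantaneous state (exact for γ=1)
            e_bar = 0.5 * (pop.E + pop.E2)
            mean_dex = (1.0 - e_bar) * lam / g + e_bar * lam + a * (1.0 - e_bar) * lam / g + d_ * b * f_aa
            n_dex = rng.poisson(mean_dex)
            t_dex = np.sort(_window_times(rng, n_dex, t0, dur_b, alex, 0))
            # two-state Markov trajectory sampled at photon times
            states = np.zeros(n_dex, dtype=np.int8)
            state = int(rng.random() < pop.k12 / max(pop.k12 + pop.k21, 1e-12))
            t_prev = t0
            for i, tp in enumerate(t_dex):
                rate = pop.k12 if state == 0 else pop.k21
                # probability of an odd number of switches is well approximated
                # by simulating exponential dwell times across the interval
                t_cur = t_prev
                while True:
                    dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                    if t_cur + dwell > tp:
                        break
                    t_cur += dwell
                    state = 1 - state
                    rate = pop.k12 if state == 0 else pop.k21
                states[i] = state
                t_prev = tp
            e_state = np.where(states == 0, pop.E, pop.E2)
            p_acc = (e_state + a * (1.0 - e_state) / g) / (
                e_state + (1.0 + a) * (1.0 - e_state) / g
            )
            acc = rng.random(n_dex) < p_acc
            times_all.append(t_dex)
            chan_all.append(acc.astype(np.int8))
            e_true = e_bar
        truth_rows.append(
            {
                "t_start": t0,
                "duration": dur_b,
                "species": int(species[k]),
                "E_true": e_true,
                "S_true": pop.S,
                "dynamic": pop.dynamic,
                "n_photons": int(n_dex + n_aa),
            }
        )

    # background, per stream, uniform over the corresponding windows
    for stream, rate in config.background.items():
        n_bg = rng.poisson(rate * duration)
        window = 0 if stream.endswith("d") else 1
        chan = 1 if stream.startswith("a") else 0
        t_bg = _window_times(rng, n_bg, 0.0, duration, alex, window)
        t_bg = t_bg[t_bg < duration]
        times_all.append(t_bg)
        chan_all.append(np.full(len(t_bg), chan, dtype=np.int8))

    times = np.concatenate(times_all)
    chans = np.concatenate(chan_all)
    order = np.argsort(times, kind="stable")
    times, chans = times[order], chans[order]
    ticks = np.round(times * config.clock_rate).astype(np.int64)

    stream = {
        "timestamps": ticks,
        "detectors": chans,
        "clock_rate": config.clock_rate,
        "alex": alex,
    }
    return stream, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# HDX uptake
# ---------------------------------------------------------------------------

HDX_TIMEPOINTS = (0.5, 2.0, 30.0, 120.0)  # minutes
D_FRACTION = 0.82  # deuterium fraction of the labelling buffer


@dataclass
class HdxPeptideProfile:
    """Lumped exchange kinetics for one peptide.

    ``rates`` are intrinsic amide exchange rates (min⁻¹), one per exchangeable
    amide; ``pf_bound`` is the protection factor applied in the bound state
    (> 1 protects, < 1 deprotects, 1 = no change).
    """

    start: int
    end: int
    sequence: str
    rates: np.ndarray
    pf_bound: float = 1.0

    def uptake(self, t_min: float, bound: bool, d_fraction: float = D_FRACTION) -> float:
        pf = self.pf_bound if bound else 1.0
        if pf <= 0:
            raise ValueError("protection factor must be > 0")
        return float(d_fraction * np.sum(1.0 - np.exp(-self.rates * t_min / pf)))


def make_hdx_profiles(
    n_peptides: int = 50,
    n_amides: tuple[int, int] = (4, 12),
    protected: dict[int, float] | None = None,
    seed: int = 0,
) -> list[HdxPeptideProfile]:
    """Random peptide set with lognormal amide rate classes.

    ``protected`` maps peptide index -> bound-state protection factor.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    pos = 1
    letters = "ACDEFGHIKLMNPQRSTVWY"
    for i in range(n_peptides):
        n_am = int(rng.integers(n_amides[0], n_amides[1] + 1))
        # amide rates spanning slow to fast exchange on the 0.5-120 min window
        rates = 10.0 ** rng.uniform(-2.5, 0.5, n_am)
        seq = "".join(rng.choice(list(letters), n_am + 1))
        pf = (protected or {}).get(i, 1.0)
        profiles.append(HdxPeptideProfile(start=pos, end=pos + n_am, sequence=seq, rates=rates, pf_bound=pf))
        pos += n_am + 1
    return profiles


def simulate_hdx(
    profiles: list[HdxPeptideProfile],
    timepoints: tuple[float, ...] = HDX_TIMEPOINTS,
    replicates: int = 4,
    noise_sd: float = 0.05,
    d_fraction: float = D_FRACTION,
    seed: int = 0,
    state_a: str = "apo",
    state_b: str = "bound",
) -> pd.DataFrame:
    """Simulate replicate uptake tables for two states (long format).

    uptake(t) = d_fraction · Σ_amides (1 − e^(−k·t/PF)) + Gaussian noise,
    with PF = 1 in state A and the per-peptide ``pf_bound`` in state B.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in profiles:
        for state, bound in ((state_a, False), (state_b, True)):
            for t in timepoints:
                base = p.uptake(t, bound, d_fraction)
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "start": p.start,
                            "end": p.end,
                            "sequence": p.sequence,
                            "state": state,
                            "exposure": t,
                            "replicate": rep,
                            "uptake": max(base + rng.normal(0.0, noise_sd), 0.0),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binding isotherms
# ---------------------------------------------------------------------------


def simulate_isotherm(
    s_u: float = 0.0,
    s_b: float = 1.0,
    kd: float = 8e-7,
    n: float = 1.0,
    top: float = 1e-4,
    n_points: int = 16,
    dilution: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill isotherm on a serial-dilution series plus Gaussian noise.

    Defaults mirror a 16-point twofold dilution from 100 μM (lowest point
    ~3 nM) around K_D = 800 nM.
    """
    if n_points < 4:
        raise ValueError("need at least 4 concentrations")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    conc = top / dilution ** np.arange(n_points)
    signal = s_u + (s_b - s_u) * conc**n / (kd**n + conc**n)
    signal = signal + rng.normal(0.0, noise_sd, n_points)
    return pd.DataFrame({"concentration": conc, "signal": signal})
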