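"""ALEX smFRET burst analysis: search, correction, filtering, fits and BVA.

Freely-diffusing molecules crossing a confocal volume under alternating laser
excitation produce photon bursts split over four streams: donor and acceptor
emission under donor excitation (DD, AD) and under acceptor excitation
(DA, AA).  Per burst, apparent FRET efficiency and stoichiometry are

    E_app = AD / (AD + DD)            S_app = (AD + DD) / (AD + DD + AA)

and the corrected values follow the standard workflow: background
subtraction, donor-leakage α and direct-excitation δ corrections giving
F_A|D = AD − α·DD − δ·AA, then detection/quantum-yield normalisation γ
(F_D|D = γ·DD) and excitation normalisation β (F_A|A = AA/β):

    E = F_A|D / (F_D|D + F_A|D)       S = (F_D|D + F_A|D) / (F_D|D + F_A|D + F_A|A)

Burst variance analysis (BVA) compares the within-burst standard deviation of
E computed over consecutive windows of n donor-excitation photons with the
shot-noise limit sqrt(E(1−E)/n); excess variance flags dynamics faster than
the burst duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixtures import EfretDistribution, fit_efret_samples
from .synthetic import AlexSpec

__all__ = [
    "PhotonStream",
    "CorrectionFactors",
    "BurstSet",
    "BvaResult",
    "write_photon_hdf5",
    "read_photon_hdf5",
    "write_photon_csv",
    "read_photon_csv",
    "estimate_background",
    "search_bursts",
    "correct_bursts",
    "estimate_factors",
    "alex_2cde",
    "filter_bursts",
    "fit_efret_distribution",
    "bva",
    "shot_noise_sd",
]

DONOR, ACCEPTOR = 0, 1


@dataclass
class PhotonStream:
    """Timestamped two-detector photon records with an ALEX alternation spec."""

    timestamps: np.ndarray  # int64 clock ticks, non-decreasing
    detectors: np.ndarray  # 0 = donor channel, 1 = acceptor channel
    clock_rate: float  # Hz
    alex: AlexSpec = field(default_factory=AlexSpec)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.detectors = np.asarray(self.detectors, dtype=np.int8)
        if len(self.timestamps) != len(self.detectors):
            raise ValueError("timestamps and detectors must have equal length")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")

    @classmethod
    def from_dict(cls, d: dict) -> "PhotonStream":
        return cls(
            timestamps=d["timestamps"], detectors=d["detectors"],
            clock_rate=d["clock_rate"], alex=d.get("alex", AlexSpec()),
        )

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps / self.clock_rate

    @property
    def duration(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if len(self.timestamps) else 0.0

    def excitation(self) -> np.ndarray:
        """Per-photon excitation window: 0 = donor, 1 = acceptor, -1 = dark.

        Computed on integer clock ticks when the alternation period is a
        whole number of ticks, so classification is exact and invariant under
        global shifts by whole periods.
        """
        period_ticks = self.alex.period_s * self.clock_rate
        if abs(period_ticks - round(period_ticks)) < 1e-6:
            pt = int(round(period_ticks))
            frac = (self.timestamps % pt) / pt
            out = np.full(len(frac), -1, dtype=np.int8)
            dw, aw = self.alex.donor_window, self.alex.acceptor_window
            out[(frac >= dw[0]) & (frac < dw[1])] = 0
            out[(frac >= aw[0]) & (frac < aw[1])] = 1
            return out
        return self.alex.excitation_of(self.times_s)

    def stream_labels(self) -> np.ndarray:
        """Four-stream label per photon: 'dd', 'ad', 'da', 'aa' or '' (dark)."""
        exc = self.excitation()
        det = self.detectors
        lab = np.full(len(det), "", dtype="U2")
        lab[(det == DONOR) & (exc == 0)] = "dd"
        lab[(det == ACCEPTOR) & (exc == 0)] = "ad"
        lab[(det == DONOR) & (exc == 1)] = "da"
        lab[(det == ACCEPTOR) & (exc == 1)] = "aa"
        return lab


# -- container I/O ---------------------------------------------------------


def write_photon_hdf5(stream: PhotonStream, path: str) -> None:
    """Write a minimal Photon-HDF5-style container (h5py)."""
    import h5py

    with h5py.File(path, "w") as f:
        pd_grp = f.create_group("photon_data")
        pd_grp.create_dataset("timestamps", data=stream.timestamps)
        pd_grp.create_dataset("detectors", data=stream.detectors.astype(np.uint8))
        ts = pd_grp.create_group("timestamps_specs")
        ts.create_dataset("timestamps_unit", data=1.0 / stream.clock_rate)
        ms = pd_grp.create_group("measurement_specs")
        ms.create_dataset("measurement_type", data=np.bytes_("smFRET-usALEX"))
        ms.create_dataset("alex_period", data=int(round(stream.alex.period_s * stream.clock_rate)))
        ms.create_dataset("alex_excitation_period1", data=np.array(stream.alex.donor_window))
        ms.create_dataset("alex_excitation_period2", data=np.array(stream.alex.acceptor_window))
        det = ms.create_group("detectors_specs")
        det.create_dataset("spectral_ch1", data=DONOR)
        det.create_dataset("spectral_ch2", data=ACCEPTOR)


def read_photon_hdf5(path: str) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        unit = float(g["timestamps_specs/timestamps_unit"][()])
        ms = g["measurement_specs"]
        period = int(ms["alex_period"][()]) * unit
        alex = AlexSpec(
            period_s=period,
            donor_window=tuple(ms["alex_excitation_period1"][()]),
            acceptor_window=tuple(ms["alex_excitation_period2"][()]),
        )
        return PhotonStream(
            timestamps=g["timestamps"][()].astype(np.int64),
            detectors=g["detectors"][()].astype(np.int8),
            clock_rate=1.0 / unit,
            alex=alex,
        )


def write_photon_csv(stream: PhotonStream, path: str) -> None:
    """Plain-text fallback: header comments carry the clock and ALEX spec."""
    a = stream.alex
    header = (
        f"# clock_rate={stream.clock_rate}\n"
        f"# alex_period_s={a.period_s}\n"
        f"# donor_window={a.donor_window[0]},{a.donor_window[1]}\n"
        f"# acceptor_window={a.acceptor_window[0]},{a.acceptor_window[1]}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("timestamp,detector\n")
        for t, d in zip(stream.timestamps, stream.detectors):
            fh.write(f"{t},{d}\n")


def read_photon_csv(path: str) -> PhotonStream:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_meta = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_meta += 1
        key, val = line[1:].strip().split("=", 1)
        meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=n_meta)
    dw = tuple(float(x) for x in meta["donor_window"].split(","))
    aw = tuple(float(x) for x in meta["acceptor_window"].split(","))
    return PhotonStream(
        timestamps=df["timestamp"].to_numpy(np.int64),
        detectors=df["detector"].to_numpy(np.int8),
        clock_rate=float(meta["clock_rate"]),
        alex=AlexSpec(period_s=float(meta["alex_period_s"]), donor_window=dw, acceptor_window=aw),
    )


# -- background ------------------------------------------------------------


def _tail_rate(delays: np.ndarray, q: float = 90.0) -> float:
    """Censored-exponential MLE of the background rate from the delay tail.

    Delays above the ``q``-th percentile are background-dominated even when
    bursts are present; the exponential tail above a threshold ``th`` has
    mean ``th + 1/rate``.
    """
    if len(delays) < 10:
        raise ValueError("too few photons for background estimation")
    th = np.percentile(delays, q)
    tail = delays[delays > th]
    if len(tail) == 0:
        return 1.0 / max(np.mean(delays), 1e-12)
    return 1.0 / max(np.mean(tail) - th, 1e-12)


def estimate_background(stream: PhotonStream, slice_s: float = 30.0) -> dict:
    """Background rates (Hz) per photon stream and for the merged stream.

    Rates are window-averaged (a stream confined to 40% of the period reports
    its photon rate over total time).  Estimated per ``slice_s`` slice and
    averaged; falls back to the whole trace with a warning when the trace is
    shorter than one slice.
    """
    t = stream.times_s
    labels = stream.stream_labels()
    duration = stream.duration
    if duration < slice_s:
        warnings.warn("trace shorter than one background slice; using whole trace")
        edges = np.array([t[0], t[-1] + 1e-9])
    else:
        edges = np.arange(t[0], t[-1] + slice_s, slice_s)
    out: dict[str, float] = {}
    for lab in ("dd", "ad", "da", "aa", "all"):
        sel = labels != "" if lab == "all" else labels == lab
        rates = []
        for a, b in zip(edges, edges[1:]):
            tt = t[sel & (t >= a) & (t < b)]
            if len(tt) < 10:
                continue
            rates.append(_tail_rate(np.diff(tt)))
        out[lab] = float(np.mean(rates)) if rates else 0.0
    return out


# -- burst search ----------------------------------------------------------


@dataclass
class BurstSet:
    """Detected bursts plus the classified photon arrays they index into."""

    times: np.ndarray  # photon times (s), dark-window photons removed
    detectors: np.ndarray
    excitation: np.ndarray  # 0 Dex / 1 Aex
    bursts: pd.DataFrame  # istart/istop (inclusive) into the arrays + counts
    background: dict

    def __len__(self) -> int:
        return len(self.bursts)

    def burst_photons(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        row = self.bursts.iloc[k]
        sl = slice(int(row["istart"]), int(row["istop"]) + 1)
        return self.times[sl], self.detectors[sl], self.excitation[sl]


def search_bursts(
    stream: PhotonStream,
    m: int = 10,
    rate_factor: float = 1.7,
    min_size: int = 20,
    background: dict | None = None,
    significance: float = 1e-6,
) -> BurstSet:
    """All-photon sliding-window burst search.

    A window of ``m`` consecutive photons qualifies when its local rate is at
    least ``rate_factor`` times the merged background rate; maximal runs of
    qualifying window starts are merged into candidate bursts, candidates
    below ``min_size`` photons are dropped, and — because at a low rate
    factor Poisson background alone satisfies the local-rate criterion with
    appreciable probability — a candidate is kept only when its total photon
    count is inconsistent with background (one-sided Poisson tail probability
    at most ``significance``).
    """
    from scipy.stats import poisson
    if background is None:
        background = estimate_background(stream)
    bg_all = background["all"]
    if bg_all <= 0:
        raise ValueError("non-positive background rate")

    exc = stream.excitation()
    keep = exc >= 0
    t = stream.times_s[keep]
    det = stream.detectors[keep]
    exc = exc[keep]
    n = len(t)
    marked = np.zeros(max(n - m + 1, 0), dtype=bool)
    if n >= m:
        span = t[m - 1 :] - t[: n - m + 1]
        # local rate m/span >= F * bg  <=>  span <= m / (F * bg); a mark means
        # the window *starting* at that photon is burst-like
        marked = span <= m / (rate_factor * bg_all)

    # maximal runs of qualifying window starts; each run [a, b) covers photons
    # a .. b-1+m-1 (the last window extends m-1 photons past its start)
    padded = np.concatenate([[False], marked, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    rows = []
    for a, b in zip(edges[::2], edges[1::2]):
        b_ph = min(b - 1 + m, n)  # exclusive photon end
        size = b_ph - a
        if size < min_size:
            continue
        expected = bg_all * max(t[b_ph - 1] - t[a], 1e-9)
        if poisson.sf(size - 1, expected) > significance:
            continue  # consistent with background alone
        sl = slice(a, b_ph)
        b = b_ph
        d, e = det[sl], exc[sl]
        rows.append(
            {
                "istart": a,
                "istop": b - 1,
                "t_start": t[a],
                "t_stop": t[b - 1],
                "duration": t[b - 1] - t[a],
                "size": size,
                "n_dd": int(((d == DONOR) & (e == 0)).sum()),
                "n_ad": int(((d == ACCEPTOR) & (e == 0)).sum()),
                "n_da": int(((d == DONOR) & (e == 1)).sum()),
                "n_aa": int(((d == ACCEPTOR) & (e == 1)).sum()),
            }
        )
    bursts = pd.DataFrame(
        rows,
        columns=["istart", "istop", "t_start", "t_stop", "duration", "size",
                 "n_dd", "n_ad", "n_da", "n_aa"],
    )
    return BurstSet(times=t, detectors=det, excitation=exc, bursts=bursts, background=background)


# -- corrections -----------------------------------------------------------


@dataclass
class CorrectionFactors:
    """α donor leakage, δ direct acceptor excitation, γ and β normalisations."""

    alpha: float = 0.0
    delta: float = 0.0
    gamma: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.delta, self.gamma, self.beta) < 0:
            raise ValueError("correction factors must be >= 0")


def _bg_corrected(bset: BurstSet) -> pd.DataFrame:
    df = bset.bursts.copy()
    bg = bset.background
    for s in ("dd", "ad", "da", "aa"):
        df[f"c_{s}"] = df[f"n_{s}"] - bg.get(s, 0.0) * df["duration"]
    return df


def estimate_factors(
    bset: BurstSet,
    do_s_min: float = 0.85,
    ao_s_max: float = 0.15,
    gamma_beta: tuple[float, float] | None = None,
    alex2cde_max: float | None = 10.0,
) -> CorrectionFactors:
    """Estimate α and δ from donor-only / acceptor-only subpopulations.

    α = E_app^(DO) / (1 − E_app^(DO)) from the background-corrected apparent E
    of donor-only bursts (S_app above ``do_s_min``); δ likewise from the
    apparent S of acceptor-only bursts.  γ and β may be supplied, or are
    estimated by the two-population regression of 1/S_app vs E_app
    (1/S = 1 + βγ + β(1−γ)E) over FRET bursts after α/δ correction.
    """
    df = _bg_corrected(bset)
    dex = df["c_dd"] + df["c_ad"]
    tot = dex + df["c_aa"]
    valid = (dex > 0) & (tot > 0)
    e_app = np.where(valid, df["c_ad"] / dex.clip(lower=1e-12), np.nan)
    s_app = np.where(valid, dex / tot.clip(lower=1e-12), np.nan)

    do = valid & (s_app > do_s_min)
    ao = valid & (s_app < ao_s_max) & (df["c_aa"] > 0)
    if do.sum() < 10 or ao.sum() < 10:
        raise ValueError(
            f"too few calibration bursts (donor-only {int(do.sum())}, acceptor-only {int(ao.sum())})"
        )
    e_do = float(np.nansum(df.loc[do, "c_ad"]) / np.nansum(dex[do]))
    alpha = e_do / (1.0 - e_do)
    s_ao = float(np.nansum(dex[ao]) / np.nansum(tot[ao]))
    delta = s_ao / (1.0 - s_ao)

    if gamma_beta is not None:
        gamma, beta = gamma_beta
    else:
        # two-population method: 1/S_app = Ω + Σ·E_app is linear across FRET
        # species; fitting through the two population centroids (ratio-of-sums
        # statistics) avoids the errors-in-variables bias of a per-burst
        # regression
        fret = valid & (s_app > 0.3) & (s_app < 0.8)
        if alex2cde_max is not None:
            # merged bursts (two molecules in the volume) corrupt population
            # centroids; the ALEX-2CDE score flags them
            fret &= alex_2cde(bset) <= alex2cde_max
        f_ad = df["c_ad"] - alpha * df["c_dd"] - delta * df["c_aa"]
        dex_c = df["c_dd"] + f_ad
        e_iii = (f_ad / dex_c.clip(lower=1e-12))[fret]
        sub = df.loc[fret][np.isfinite(e_iii)]
        good = e_iii[np.isfinite(e_iii)].to_numpy()
        if len(good) < 100:
            raise ValueError("too few FRET bursts to estimate gamma/beta; supply them explicitly")
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=2, n_init=3, random_state=0)
        gm.fit(good.reshape(-1, 1))
        lab = gm.predict(good.reshape(-1, 1))
        pts = []
        for c in (0, 1):
            e_c = good[lab == c]
            if len(e_c) < 20:
                continue
            # trim to the central mass of the cluster so stray single-labelled
            # bursts do not drag the centroid
            lo, hi = np.percentile(e_c, [10, 90])
            rows = sub[(lab == c) & (good >= lo) & (good <= hi)]
            f_ad_c = rows["c_ad"] - alpha * rows["c_dd"] - delta * rows["c_aa"]
            dex_cc = rows["c_dd"] + f_ad_c
            e_pop = float(f_ad_c.sum() / dex_cc.sum())
            sinv_pop = float((dex_cc + rows["c_aa"]).sum() / dex_cc.sum())
            pts.append((e_pop, sinv_pop))
        if len(pts) < 2 or abs(pts[0][0] - pts[1][0]) < 0.1:
            raise ValueError(
                "gamma/beta estimation needs two FRET populations separated in E; "
                "supply gamma_beta explicitly"
            )
        (e1, s1), (e2, s2) = pts
        sigma_ = (s2 - s1) / (e2 - e1)
        omega = s1 - sigma_ * e1
        beta = omega + sigma_ - 1.0
        gamma = (omega - 1.0) / beta
    return CorrectionFactors(alpha=alpha, delta=delta, gamma=gamma, beta=beta)


def correct_bursts(
    bset: BurstSet, factors: CorrectionFactors | None = None
) -> pd.DataFrame:
    """Apply the full correction pipeline and return the burst table with E, S.

    Pipeline: background subtraction → α, δ (F_A|D = AD − α·DD − δ·AA) →
    γ, β (F_D|D = γ·DD, F_A|A = AA/β) → E, S.  ``e_app``/``s_app`` are the
    uncorrected apparent values; bursts whose corrected denominators are
    non-positive are flagged invalid.
    """
    if factors is None:
        factors = estimate_factors(bset)
    df = _bg_corrected(bset)

    dex_raw = df["n_dd"] + df["n_ad"]
    tot_raw = dex_raw + df["n_aa"]
    df["e_app"] = np.where(dex_raw > 0, df["n_ad"] / dex_raw.replace(0, np.nan), np.nan)
    df["s_app"] = np.where(tot_raw > 0, dex_raw / tot_raw.replace(0, np.nan), np.nan)

    f_ad = df["c_ad"] - factors.alpha * df["c_dd"] - factors.delta * df["c_aa"]
    f_dd = factors.gamma * df["c_dd"]
    f_aa = df["c_aa"] / factors.beta
    denom_e = f_dd + f_ad
    denom_s = f_dd + f_ad + f_aa
    df["f_dd"], df["f_ad"], df["f_aa"] = f_dd, f_ad, f_aa
    df["valid"] = (denom_e > 0) & (denom_s > 0)
    df["E"] = np.where(df["valid"], f_ad / denom_e.where(denom_e > 0), np.nan)
    df["S"] = np.where(df["valid"], denom_e / denom_s.where(denom_s > 0), np.nan)
    df.attrs["factors"] = factors
    return df


# -- filtering -------------------------------------------------------------


def alex_2cde(bset: BurstSet, tau: float = 100e-6) -> np.ndarray:
    """ALEX-2CDE brightness-ratio score per burst (0 ≈ well-mixed dual-label).

    Exponential-kernel densities of donor-excitation and acceptor-excitation
    photon times are compared at each photon:
    score = 100 − 50·(BR_DexAex + BR_AexDex), where each BR averages the
    cross-stream/own-stream density ratio.  Single-labelled bursts, whose two
    excitation streams are unbalanced, score near 100.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    scores = np.empty(len(bset))
    for k in range(len(bset)):
        t, _, exc = bset.burst_photons(k)
        td, ta = t[exc == 0], t[exc == 1]
        nd, na = len(td), len(ta)
        if nd < 2 or na < 2:
            scores[k] = 100.0
            continue
        # kernel sums; the own-stream density keeps the self photon so the
        # ratio denominator is always >= 1
        kde_a_at_d = np.exp(-np.abs(td[:, None] - ta[None, :]) / tau).sum(axis=1)
        kde_d_at_d = np.exp(-np.abs(td[:, None] - td[None, :]) / tau).sum(axis=1)
        kde_d_at_a = np.exp(-np.abs(ta[:, None] - td[None, :]) / tau).sum(axis=1)
        kde_a_at_a = np.exp(-np.abs(ta[:, None] - ta[None, :]) / tau).sum(axis=1)
        br_da = (kde_a_at_d / kde_d_at_d).sum() / na
        br_ad = (kde_d_at_a / kde_a_at_a).sum() / nd
        scores[k] = 100.0 - 50.0 * (br_da + br_ad)
    return scores


def filter_bursts(
    bset: BurstSet,
    corrected: pd.DataFrame,
    s_range: tuple[float, float] = (0.25, 0.75),
    alex2cde_tau: float = 100e-6,
    alex2cde_max: float | None = 10.0,
) -> pd.DataFrame:
    """Keep doubly-labelled bursts: S inside the closed window and
    ALEX-2CDE ≤ threshold (skipped when ``alex2cde_max`` is None)."""
    keep = corrected["valid"] & corrected["S"].between(s_range[0], s_range[1], inclusive="both")
    if alex2cde_max is not None:
        scores = alex_2cde(bset, tau=alex2cde_tau)
        corrected = corrected.assign(alex_2cde=scores)
        keep &= corrected["alex_2cde"] <= alex2cde_max
    return corrected[keep].copy()


def fit_efret_distribution(
    bursts: pd.DataFrame | np.ndarray,
    max_components: int = 2,
    force: int | None = None,
    seed: int = 0,
) -> EfretDistribution:
    """KDE + ≤2-Gaussian maximum-likelihood fit of corrected burst E values."""
    e = bursts["E"].to_numpy() if isinstance(bursts, pd.DataFrame) else np.asarray(bursts)
    e = e[np.isfinite(e)]
    if len(e) < 100:
        raise ValueError(f"need >= 100 bursts, got {len(e)}")
    return fit_efret_samples(e, max_components=max_components, force=force, seed=seed)


# -- burst variance analysis ----------------------------------------------


def shot_noise_sd(e, n: int):
    """Binomial shot-noise limit of window-wise E: sqrt(E(1−E)/n)."""
    e = np.asarray(e, dtype=float)
    return np.sqrt(np.clip(e * (1.0 - e), 0.0, None) / n)


@dataclass
class BvaResult:
    per_burst: pd.DataFrame  # e_prox, sd, n_windows, E (corrected, if given)
    bins: pd.DataFrame  # bin centre, mean sd, SE, n, shot-noise sd
    window: int


def bva(
    bset: BurstSet,
    window: int = 5,
    corrected: pd.DataFrame | None = None,
    n_bins: int = 20,
    min_windows: int = 2,
) -> BvaResult:
    """Burst variance analysis over donor-excitation photons.

    Per burst, the acceptor fraction E is computed in consecutive
    non-overlapping windows of ``window`` Dex photons; the standard deviation
    across windows (ddof = 1) is compared, binned by the burst's overall
    acceptor fraction, with the shot-noise curve sqrt(E(1−E)/window).
    """
    if window < 2:
        raise ValueError("window must be >= 2 photons")
    rows = []
    for k in range(len(bset)):
        _, det, exc = bset.burst_photons(k)
        acc = det[exc == 0] == ACCEPTOR
        n_win = len(acc) // window
        if n_win < min_windows:
            continue
        trimmed = acc[: n_win * window].reshape(n_win, window)
        e_win = trimmed.mean(axis=1)
        rows.append(
            {
                "burst": k,
                "e_prox": float(acc.mean()),
                "sd": float(np.std(e_win, ddof=1)),
                "n_windows": n_win,
                "E": float(corrected["E"].iloc[k]) if corrected is not None else np.nan,
            }
        )
    per_burst = pd.DataFrame(rows, columns=["burst", "e_prox", "sd", "n_windows", "E"])

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    brows = []
    for c, a, b in zip(centers, edges, edges[1:]):
        sel = per_burst[(per_burst["e_prox"] >= a) & (per_burst["e_prox"] < b)]
        if len(sel) == 0:
            continue
        mean_e = float(sel["e_prox"].mean())
        brows.append(
            {
                "e_center": c,
                "e_mean": mean_e,
                "sd_mean": float(sel["sd"].mean()),
                "sd_se": float(sel["sd"].std(ddof=1) / np.sqrt(len(sel))) if len(sel) > 1 else np.nan,
                "n": len(sel),
                "sd_shot": float(shot_noise_sd(mean_e, window)),
            }
        )
    bins = pd.DataFrame(brows, columns=["e_center", "e_mean", "sd_mean", "sd_se", "n", "sd_shot"])
    return BvaResult(per_burst=per_burst, bins=bins, window=window)
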