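"""Per-molecule smFRET trace QC, efficiency, two-state dwells and rates.

The analysis starts at background-subtracted donor/acceptor intensity
traces.  Photobleaching is located by change-point detection, traces are
accepted or rejected against single-bleach/recovery criteria, corrected
FRET efficiency is thresholded into high (wrapped) and low (unwrapped)
states, and state lifetimes are fitted as single exponentials.

Dwell times measured on frames of length ``dt`` are biased when dt is not
small against the true lifetimes: a run of L same-state frames
overestimates the sojourn by about dt/2, and opposite-state excursions
shorter than the sampling interval are missed entirely, merging adjacent
dwells.  ``fit_two_state`` inverts both effects exactly: the noiseless
frame-sampled state sequence of an alternating two-exponential process is
a first-order Markov chain whose stay probabilities map one-to-one onto
the two lifetimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

LOW, HIGH = "low_fret_unwrapped", "high_fret_wrapped"
DEFAULT_THRESHOLD = 0.48


@dataclass(frozen=True)
class CorrectionFactors:
    """Donor-to-acceptor leakage (alpha) and detection/quantum-yield ratio (gamma)."""

    alpha: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValidationError("alpha must be in [0, 1)")
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")


# ---------------------------------------------------------------------------
# change points and bleaching


def _robust_noise_sd(signal: np.ndarray) -> float:
    """Noise s.d. from the median absolute deviation of first differences."""
    d = np.diff(np.asarray(signal, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def _split_stats(signal: np.ndarray):
    """Per-split SSE of a two-mean fit, via cumulative sums.

    Returns (reduction, mean_left, mean_right) arrays indexed by k =
    1..n-1, the first frame of the right segment.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    k = np.arange(1, n)
    left_n, right_n = k, n - k
    left_sum, right_sum = cs[k - 1], cs[-1] - cs[k - 1]
    left_sse = cs2[k - 1] - left_sum**2 / left_n
    right_sse = (cs2[-1] - cs2[k - 1]) - right_sum**2 / right_n
    tss = cs2[-1] - cs[-1] ** 2 / n
    reduction = tss - (left_sse + right_sse)
    return reduction, left_sum / left_n, right_sum / right_n


def largest_change_point(signal: np.ndarray, min_effect: float | None = None) -> int | None:
    """Index of the largest change point of a two-mean piecewise fit.

    Returns the first frame of the second segment, or None when the best
    split's mean step does not exceed ``min_effect`` (default: twice the
    MAD-based noise s.d.).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise ValidationError("series too short for change-point detection (need >= 4)")
    reduction, mean_l, mean_r = _split_stats(x)
    best = int(np.argmax(reduction))
    step = abs(mean_r[best] - mean_l[best])
    if min_effect is None:
        min_effect = 2.0 * _robust_noise_sd(x)
    if step <= min_effect or step == 0.0:
        return None
    return best + 1


def _bleach_index(signal: np.ndarray, floor: float, noise_sd: float) -> int | None:
    """Largest down change point whose right-segment mean is at background.

    Candidate splits are those whose post-split mean falls below ``floor``;
    among them the split with the largest SSE reduction wins (ties keep the
    earliest).  The step must be a drop exceeding twice the noise s.d.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        return None
    reduction, mean_l, mean_r = _split_stats(x)
    ok = mean_r < floor
    if not ok.any():
        return None
    masked = np.where(ok, reduction, -np.inf)
    best = int(np.argmax(masked))
    step = mean_l[best] - mean_r[best]
    if step <= max(2.0 * noise_sd, 0.0):
        return None
    return best + 1


def _has_structure(segment: np.ndarray, min_effect: float) -> bool:
    """True when a sub-segment contains an accepted change point."""
    if segment.size < 4:
        return False
    return largest_change_point(segment, min_effect=min_effect) is not None


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class QcConfig:
    min_prebleach: int = 5        # frames of FRET required before the first bleach
    min_initial_ratio: float = 0.15  # acceptor share of initial intensity
    floor_frac: float = 0.30      # background threshold, fraction of the 95th pct
    noise_mult: float = 2.0
    recovery_window: int = 5      # frames before the acceptor bleach for recovery test
    blink_floor_frac: float = 0.12  # pre-bleach background-excursion threshold
    blink_window: int = 3


@dataclass
class QcResult:
    molecule_id: str
    status: str                   # "accepted" | "rejected"
    reason: str = ""
    acceptor_bleach: int | None = None
    donor_bleach: int | None = None
    prebleach_end: int | None = None  # exclusive frame index of the analysis window

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def qc_trace(donor: np.ndarray, acceptor: np.ndarray,
             molecule_id: str = "", config: QcConfig = QcConfig()) -> QcResult:
    """Accept or reject a two-channel trace against single-bleach criteria.

    Rules: the molecule must show acceptor signal at the start (not
    donor-only), exactly one background-reaching bleach step per channel
    with no further structure afterwards, at least ``min_prebleach`` frames
    of FRET before the earlier bleach, and donor recovery after the
    acceptor bleach.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    n = donor.size
    if n != acceptor.size:
        raise ValidationError("channel length mismatch")

    def reject(reason: str, **kw) -> QcResult:
        return QcResult(molecule_id, "rejected", reason, **kw)

    if n < max(4, config.min_prebleach + 2):
        return reject("too_short")

    head = slice(0, max(1, config.min_prebleach))
    total0 = float(np.mean(donor[head]) + np.mean(acceptor[head]))
    if total0 <= 0 or float(np.mean(acceptor[head])) / total0 < config.min_initial_ratio:
        return reject("no_acceptor")

    sd_d = _robust_noise_sd(donor)
    sd_a = _robust_noise_sd(acceptor)
    floor_d = config.floor_frac * float(np.percentile(donor, 95))
    floor_a = config.floor_frac * float(np.percentile(acceptor, 95))

    k_a = _bleach_index(acceptor, floor_a, sd_a)
    if k_a is None:
        return reject("no_acceptor_bleach")
    k_d = _bleach_index(donor, floor_d, sd_d)
    if k_d is None:
        return reject("no_donor_bleach", acceptor_bleach=k_a)

    prebleach_end = min(k_a, k_d)
    if prebleach_end < config.min_prebleach:
        return reject("short_prebleach", acceptor_bleach=k_a, donor_bleach=k_d)

    # before its bleach a channel must never dwell at background: a dark
    # excursion that recovers means more than one bleaching event (blinking
    # or a second fluorophore)
    w = config.blink_window
    for channel, k in ((acceptor, k_a), (donor, k_d)):
        pre = channel[:k]
        if pre.size >= w:
            blink_floor = config.blink_floor_frac * float(np.percentile(channel, 95))
            smooth = np.convolve(pre, np.ones(w) / w, mode="valid")
            if (smooth < blink_floor).any():
                return reject("multiple_bleach", acceptor_bleach=k_a, donor_bleach=k_d)

    # after its own bleach each channel must stay featureless (no blinking,
    # no second bleach event); check sub-windows split at the other bleach
    first, second = sorted((k_a, k_d))
    for channel, sd, k in ((acceptor, sd_a, k_a), (donor, sd_d, k_d)):
        bounds = sorted({k, max(k, first), max(k, second), n})
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if _has_structure(channel[lo:hi], 2.0 * sd):
                return reject("multiple_bleach", acceptor_bleach=k_a, donor_bleach=k_d)

    # donor recovery after acceptor bleach (anticorrelation at the bleach)
    if k_a + 1 < k_d:
        pre = donor[max(0, k_a - config.recovery_window):k_a]
        post = donor[k_a:k_d]
        if float(np.mean(post)) - float(np.mean(pre)) <= config.noise_mult * sd_d:
            return reject("no_donor_recovery", acceptor_bleach=k_a, donor_bleach=k_d)

    return QcResult(molecule_id, "accepted", "", k_a, k_d, prebleach_end)


# ---------------------------------------------------------------------------
# efficiency and dwell segmentation


def fret_efficiency(donor: np.ndarray, acceptor: np.ndarray,
                    factors: CorrectionFactors = CorrectionFactors()) -> np.ndarray:
    """Corrected FRET efficiency per frame.

    E = (I_A - alpha I_D) / (gamma I_D + I_A - alpha I_D).  Frames with a
    non-positive denominator are NaN (invalid); values are never clipped.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    fa = acceptor - factors.alpha * donor
    denom = factors.gamma * donor + fa
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(denom > 0, fa / denom, np.nan)
    return e


@dataclass(frozen=True)
class Run:
    """One uninterrupted residence in a FRET state."""

    state: str
    n_frames: int
    duration_s: float
    censored_left: bool
    censored_right: bool


@dataclass
class DwellSet:
    state: str
    dwells: list[float] = field(default_factory=list)       # seconds
    n_frames: list[int] = field(default_factory=list)
    censored_left: list[bool] = field(default_factory=list)
    censored_right: list[bool] = field(default_factory=list)

    @property
    def uncensored(self) -> list[float]:
        return [d for d, cl, cr in zip(self.dwells, self.censored_left, self.censored_right)
                if not cl and not cr]


def segment_states(efficiency: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
                   dt: float = 1.0, min_dwell_frames: int = 1) -> list[Run]:
    """Threshold an efficiency series into alternating high/low runs.

    E >= threshold classifies as high (ties high).  NaN frames continue the
    preceding state (leading NaNs are dropped).  Runs shorter than
    ``min_dwell_frames`` are merged into their neighbours.  The first and
    last runs are flagged censored.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must be in (0, 1)")
    e = np.asarray(efficiency, dtype=float)
    valid = np.isfinite(e)
    if not valid.any():
        return []
    start = int(np.argmax(valid))
    states = []
    prev = None
    for value in e[start:]:
        if np.isfinite(value):
            prev = bool(value >= threshold)
        states.append(prev)
    arr = np.array(states, dtype=bool)

    lengths, labels = _run_lengths(arr)
    lengths, labels = _merge_short(lengths, labels, min_dwell_frames)
    runs = []
    for i, (length, label) in enumerate(zip(lengths, labels)):
        runs.append(Run(
            state=HIGH if label else LOW,
            n_frames=int(length),
            duration_s=float(length) * dt,
            censored_left=(i == 0),
            censored_right=(i == len(lengths) - 1),
        ))
    return runs


def _run_lengths(arr: np.ndarray):
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    bounds = np.concatenate(([0], change, [arr.size]))
    lengths = np.diff(bounds)
    labels = arr[bounds[:-1]]
    return list(lengths), list(labels)


def _merge_short(lengths: list[int], labels, min_frames: int):
    if min_frames <= 1:
        return lengths, labels
    lengths, labels = list(lengths), list(labels)
    changed = True
    while changed and len(lengths) > 1:
        changed = False
        for i, length in enumerate(lengths):
            if length < min_frames:
                j = i - 1 if i > 0 else i + 1
                lengths[j] += lengths.pop(i)
                labels.pop(i)
                # merging may join equal-state neighbours
                merged = True
                while merged:
                    merged = False
                    for a in range(len(labels) - 1):
                        if labels[a] == labels[a + 1]:
                            lengths[a] += lengths.pop(a + 1)
                            labels.pop(a + 1)
                            merged = True
                            break
                changed = True
                break
    return lengths, labels


def dwell_sets(runs: list[Run]) -> dict[str, DwellSet]:
    """Group alternating runs into per-state dwell sets."""
    out = {LOW: DwellSet(LOW), HIGH: DwellSet(HIGH)}
    for run in runs:
        ds = out[run.state]
        ds.dwells.append(run.duration_s)
        ds.n_frames.append(run.n_frames)
        ds.censored_left.append(run.censored_left)
        ds.censored_right.append(run.censored_right)
    return out


# ---------------------------------------------------------------------------
# exponential fits


@dataclass(frozen=True)
class DwellFit:
    state: str
    tau: float           # exponential mean lifetime, s
    half_life: float     # tau * ln 2
    rate: float          # 1 / half_life (default convention) or 1 / tau
    n_dwells: int
    method: str = "mle"
    rate_convention: str = "half_life"


def _make_fit(state: str, tau: float, n: int, method: str,
              rate_convention: str = "half_life") -> DwellFit:
    half_life = tau * math.log(2.0)
    rate = 1.0 / half_life if rate_convention == "half_life" else 1.0 / tau
    return DwellFit(state, tau, half_life, rate, n, method, rate_convention)


def fit_exponential(dwells: DwellSet, censoring: str = "drop",
                    min_dwells: int = 10, dt: float | None = None,
                    quantization: str = "none",
                    rate_convention: str = "half_life") -> DwellFit:
    """Maximum-likelihood single-exponential fit of a dwell set.

    censoring="drop" uses the plain mean of uncensored dwells;
    censoring="include" uses the right-censored MLE
    (sum of all durations / number of uncensored dwells).
    quantization="midpoint" adds dt/2 to each dwell before fitting, the
    continuity correction for durations measured in whole frames.  Note
    this does not correct for opposite-state events shorter than the frame
    interval; use :func:`fit_two_state` when dt is comparable to the
    lifetimes.
    """
    if censoring not in ("drop", "include"):
        raise ValidationError(f"unknown censoring policy {censoring!r}")
    offset = 0.0
    if quantization == "midpoint":
        if dt is None:
            raise ValidationError("midpoint quantization needs dt")
        offset = dt / 2.0
    elif quantization != "none":
        raise ValidationError(f"unknown quantization {quantization!r}")

    uncensored = dwells.uncensored
    if len(uncensored) < min_dwells:
        raise ValidationError(
            f"too few uncensored dwells for {dwells.state}: {len(uncensored)} < {min_dwells}"
        )
    if censoring == "drop":
        tau = float(np.mean([d + offset for d in uncensored]))
        n = len(uncensored)
    else:
        total = float(np.sum([d + offset for d in dwells.dwells]))
        tau = total / len(uncensored)
        n = len(dwells.dwells)
    return _make_fit(dwells.state, tau, n, "mle", rate_convention)


def fit_two_state(runs_per_molecule: list[list[Run]], dt: float,
                  min_dwells: int = 10,
                  rate_convention: str = "half_life") -> dict[str, DwellFit]:
    """Lifetimes from frame-sampled two-state data, sampling-bias corrected.

    The instantaneous state sampled every ``dt`` seconds from an
    alternating process with exponential lifetimes (tau_low, tau_high) is a
    two-state Markov chain with stay probabilities
    p_ss = pi_s + (1 - pi_s) exp(-lambda dt), lambda = 1/tau_low +
    1/tau_high.  The chain MLE of (p_LL, p_HH) is inverted in closed form,
    which corrects both frame quantization and opposite-state events
    shorter than the frame interval.
    """
    stay = {LOW: 0, HIGH: 0}    # same-state frame-to-frame transitions
    leave = {LOW: 0, HIGH: 0}   # observed exits
    n_runs = {LOW: 0, HIGH: 0}
    for runs in runs_per_molecule:
        for run in runs:
            stay[run.state] += run.n_frames - 1
            n_runs[run.state] += 1
            if not run.censored_right:
                leave[run.state] += 1
    for state in (LOW, HIGH):
        if leave[state] < min_dwells:
            raise ValidationError(
                f"too few observed {state} exits: {leave[state]} < {min_dwells}"
            )
    p_ll = stay[LOW] / (stay[LOW] + leave[LOW])
    p_hh = stay[HIGH] / (stay[HIGH] + leave[HIGH])
    e = p_ll + p_hh - 1.0
    if e <= 0.0:
        raise ValidationError(
            "sampled chain inconsistent with an alternating process (p_LL + p_HH <= 1); "
            "frame interval too long for these lifetimes"
        )
    lam = -math.log(e) / dt
    pi_low = (p_ll - e) / (1.0 - e)
    tau_low = 1.0 / (lam * (1.0 - pi_low))
    tau_high = 1.0 / (lam * pi_low)
    return {
        LOW: _make_fit(LOW, tau_low, n_runs[LOW], "markov", rate_convention),
        HIGH: _make_fit(HIGH, tau_high, n_runs[HIGH], "markov", rate_convention),
    }


def fit_exponential_histogram(dwells: DwellSet, dt: float,
                              min_dwells: int = 10,
                              rate_convention: str = "half_life") -> DwellFit:
    """Least-squares fit of an exponential to the dwell-time histogram.

    Retained for comparison with the MLE route; bins are one frame wide.
    """
    uncensored = np.array(dwells.uncensored)
    if uncensored.size < min_dwells:
        raise ValidationError("too few uncensored dwells")
    edges = np.arange(0.0, uncensored.max() + 2 * dt, dt)
    counts, edges = np.histogram(uncensored, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    # log-linear least squares on nonzero bins
    slope, intercept = np.polyfit(centers[keep], np.log(counts[keep]), 1)
    if slope >= 0:
        raise ValidationError("histogram fit did not decay")
    tau = -1.0 / slope
    return _make_fit(dwells.state, float(tau), int(uncensored.size),
                     "histogram", rate_convention)


# ---------------------------------------------------------------------------
# replicate comparison and pipeline


def compare_replicates(values_a, values_b) -> tuple[float, float]:
    """Classical unpaired two-sided Student's t-test (pooled variance)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def analyze_traces(traces, factors: CorrectionFactors,
                   threshold: float = DEFAULT_THRESHOLD,
                   qc_config: QcConfig = QcConfig(),
                   min_dwell_frames: int = 1,
                   min_dwells: int = 10,
                   method: str = "markov",
                   rate_convention: str = "half_life") -> dict:
    """Full per-molecule QC -> efficiency -> segmentation -> lifetime fits.

    ``traces`` is a trace table (io_formats.read_traces).  Returns a dict
    with per-molecule QC results, runs per accepted molecule, pooled dwell
    sets and per-state DwellFits.  ``method`` selects the sampling-bias
    corrected two-state inversion ("markov", default) or the plain dwell
    mean with midpoint correction ("midpoint") or none ("naive").
    """
    qc_results: list[QcResult] = []
    runs_per_molecule: list[list[Run]] = []
    dt_values = []
    for mol, grp in traces.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame_index")
        donor = grp["donor"].to_numpy(float)
        acceptor = grp["acceptor"].to_numpy(float)
        t = grp["time_s"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        qc = qc_trace(donor, acceptor, molecule_id=str(mol), config=qc_config)
        qc_results.append(qc)
        if not qc.accepted:
            continue
        dt_values.append(dt)
        window = slice(0, qc.prebleach_end)
        e = fret_efficiency(donor[window], acceptor[window], factors)
        runs = segment_states(e, threshold=threshold, dt=dt,
                              min_dwell_frames=min_dwell_frames)
        runs_per_molecule.append(runs)

    pooled = {LOW: DwellSet(LOW), HIGH: DwellSet(HIGH)}
    for runs in runs_per_molecule:
        for state, ds in dwell_sets(runs).items():
            pooled[state].dwells.extend(ds.dwells)
            pooled[state].n_frames.extend(ds.n_frames)
            pooled[state].censored_left.extend(ds.censored_left)
            pooled[state].censored_right.extend(ds.censored_right)

    fits: dict[str, DwellFit] = {}
    fit_error = ""
    if runs_per_molecule:
        dt = float(np.median(dt_values))
        try:
            if method == "markov":
                fits = fit_two_state(runs_per_molecule, dt, min_dwells=min_dwells,
                                     rate_convention=rate_convention)
            else:
                quant = "midpoint" if method == "midpoint" else "none"
                for state in (LOW, HIGH):
                    fits[state] = fit_exponential(
                        pooled[state], censoring="drop", min_dwells=min_dwells,
                        dt=dt, quantization=quant, rate_convention=rate_convention)
        except ValidationError as exc:
            fits, fit_error = {}, str(exc)
    return {
        "qc": qc_results,
        "runs_per_molecule": runs_per_molecule,
        "dwell_sets": pooled,
        "fits": fits,
        "fit_error": fit_error,
    }
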