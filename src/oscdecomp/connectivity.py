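"""Frequency-specific functional connectivity from decomposed oscillators.

For a target frequency band, each channel contributes the smoothed bivariate
trajectory of its maximum-power in-band oscillator; every channel pair is
scored by the first canonical correlation between the two trajectories, and
thresholding the resulting matrix yields a network.  Channel pairs are
grouped into short-range, contralateral-transverse, ipsilateral-longitudinal
and control connectivity classes for group-level summaries.  A conventional
baseline (Pearson correlation of bandpassed signals) is also provided.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "PAIR_GROUPS",
    "ChannelLayout",
    "default_layout",
    "ConnectivityNetwork",
    "select_band_oscillator",
    "canonical_corr",
    "build_network",
    "group_connectivity",
    "average_networks",
    "corr_connectivity",
]

PAIR_GROUPS = (
    "short_range",
    "contralateral_transverse",
    "ipsilateral_longitudinal",
    "control",
)

_LABEL_RE = re.compile(r"^([LR])(\d+)$")


@dataclass(frozen=True)
class ChannelLayout:
    """Channel labels with hemisphere/position structure and pair grouping.

    Labels follow the ``L<i>`` / ``R<i>`` convention: hemisphere letter plus
    a within-hemisphere position index running front to back.  The default
    grouping rule assigns each unordered channel pair to one of four classes:

    * ``short_range`` -- same hemisphere, adjacent positions (|i - j| = 1);
    * ``contralateral_transverse`` -- opposite hemispheres, |i - j| <= 1
      (homologous and near-homologous pairs);
    * ``ipsilateral_longitudinal`` -- same hemisphere, distant positions
      (|i - j| >= 5);
    * ``control`` -- everything else.

    For the full 18-channel layout (L1-L9, R1-R9) the four groups contain
    16, 25, 20 and 92 of the 153 unordered pairs.
    """

    labels: tuple
    longitudinal_min_gap: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        for lab in self.labels:
            if not _LABEL_RE.match(lab):
                raise ValueError(f"channel label {lab!r} does not match the L<i>/R<i> convention")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")

    def hemisphere(self, label: str) -> str:
        return _LABEL_RE.match(label).group(1)

    def position(self, label: str) -> int:
        return int(_LABEL_RE.match(label).group(2))

    def pair_group(self, lab1: str, lab2: str) -> str:
        if lab1 == lab2:
            raise ValueError("pair group is undefined for identical channels")
        h1, h2 = self.hemisphere(lab1), self.hemisphere(lab2)
        gap = abs(self.position(lab1) - self.position(lab2))
        if h1 == h2:
            if gap == 1:
                return "short_range"
            if gap >= self.longitudinal_min_gap:
                return "ipsilateral_longitudinal"
            return "control"
        if gap <= 1:
            return "contralateral_transverse"
        return "control"

    def pair_groups(self) -> dict:
        """Mapping from each unordered label pair to its group."""
        return {frozenset(p): self.pair_group(*p) for p in combinations(self.labels, 2)}

    def group_sizes(self) -> dict:
        sizes = dict.fromkeys(PAIR_GROUPS, 0)
        for g in self.pair_groups().values():
            sizes[g] += 1
        return sizes


def default_layout(labels=None) -> ChannelLayout:
    """The 18-channel layout L1..L9, R1..R9 (or a subset of such labels)."""
    if labels is None:
        labels = tuple(f"{h}{i}" for h in "LR" for i in range(1, 10))
    return ChannelLayout(labels=tuple(labels))


# ---------------------------------------------------------------------------
# oscillator selection and canonical correlation
# ---------------------------------------------------------------------------


def _phase_class_of(model, k: int) -> str:
    d = model.phase_delay_deg(1, k)
    return "in_phase" if min(d, 360.0 - d) < 90.0 else "anti_phase"


def select_band_oscillator(decomp, band, phase_class: str | None = None) -> int | None:
    """Index of the maximum-power oscillator inside a frequency band.

    ``decomp`` is a DecompResult (or any object with a ``best.model``); power
    is the latent stationary variance sigma2/(1-a^2).  ``phase_class``
    optionally restricts to oscillators whose deoxy phase delay is within 90
    degrees of 0 (``"in_phase"``) or of 180 (``"anti_phase"``), which
    separates pulse-wave from mirroring-noise components sharing the cardiac
    band.  Returns None when no oscillator qualifies.  Ties break toward the
    lower index.
    """
    lo, hi = band
    model = decomp.best.model if hasattr(decomp, "best") else decomp
    best_idx, best_power = None, -np.inf
    for k, osc in enumerate(model.oscillators):
        if not lo <= osc.f <= hi:
            continue
        if phase_class is not None and _phase_class_of(model, k) != phase_class:
            continue
        if osc.power > best_power:
            best_idx, best_power = k, osc.power
    return best_idx


def canonical_corr(X: np.ndarray, Y: np.ndarray) -> float:
    """First canonical correlation between two multivariate samples.

    ``X`` (N x p) and ``Y`` (N x q) are centered; the maximal Pearson
    correlation over linear projections a'X, b'Y equals the largest singular
    value of the whitened cross-covariance and solves the generalized
    eigenvalue problem of CCA.  Rank-deficient within-set covariances are
    ridge-regularized with a warning.  The result is clipped to [0, 1].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / n
    Syy = Yc.T @ Yc / n
    Sxy = Xc.T @ Yc / n

    def chol_safe(S, name):
        scale = np.trace(S) / S.shape[0]
        if scale <= 0:
            raise ValueError(f"{name} has zero variance")
        try:
            return np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            warnings.warn(f"rank-deficient within-set covariance for {name}; ridge-regularizing")
            return np.linalg.cholesky(S + 1e-10 * scale * np.eye(S.shape[0]))

    Lx = chol_safe(Sxx, "X")
    Ly = chol_safe(Syy, "Y")
    M = np.linalg.solve(Lx, Sxy)
    M = np.linalg.solve(Ly, M.T).T
    r = float(np.linalg.svd(M, compute_uv=False)[0])
    return min(max(r, 0.0), 1.0)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityNetwork:
    """Channel-pair canonical correlations in one frequency band.

    ``r_matrix`` is symmetric with NaN on the diagonal and for pairs where
    at least one channel has no qualifying oscillator.
    """

    band: tuple
    labels: tuple
    r_matrix: np.ndarray
    phase_class: str | None = None
    n_subjects: int = 1
    thresholds: tuple = (0.7, 0.6, 0.5, 0.4)

    def adjacency(self, threshold: float) -> np.ndarray:
        """Boolean connection matrix; missing entries are unconnected."""
        with np.errstate(invalid="ignore"):
            return np.where(np.isnan(self.r_matrix), False, self.r_matrix >= threshold)

    def edge_fraction(self, threshold: float) -> float:
        """Fraction of available (non-missing) pairs connected at a threshold."""
        iu = np.triu_indices(len(self.labels), 1)
        r = self.r_matrix[iu]
        ok = ~np.isnan(r)
        if not ok.any():
            return float("nan")
        return float(np.mean(r[ok] >= threshold))


def build_network(
    decomps: dict,
    band,
    layout: ChannelLayout | None = None,
    phase_class: str | None = None,
    trajectories: dict | None = None,
) -> ConnectivityNetwork:
    """Network of canonical correlations between in-band oscillators.

    ``decomps`` maps channel labels to DecompResults; each channel's smoothed
    bivariate trajectory of its selected oscillator enters the pairwise CCA.
    ``trajectories`` may override the smoothed trajectories (label ->
    (N, 2) array) for channels whose selection should be bypassed.
    Channels without an in-band oscillator yield NaN rows/columns.
    """
    labels = tuple(decomps)
    layout = layout or default_layout(labels)
    traj = {}
    for lab, dec in decomps.items():
        if trajectories is not None and lab in trajectories:
            traj[lab] = trajectories[lab]
            continue
        k = select_band_oscillator(dec, band, phase_class=phase_class)
        if k is None:
            continue
        traj[lab] = dec.trajectory.means[:, 2 * k : 2 * k + 2]
    c = len(labels)
    r = np.full((c, c), np.nan)
    for i, j in combinations(range(c), 2):
        li, lj = labels[i], labels[j]
        if li in traj and lj in traj:
            r[i, j] = r[j, i] = canonical_corr(traj[li], traj[lj])
    return ConnectivityNetwork(band=tuple(band), labels=labels, r_matrix=r, phase_class=phase_class)


def average_networks(networks) -> ConnectivityNetwork:
    """Entry-wise mean network across subjects, ignoring missing entries."""
    networks = list(networks)
    if not networks:
        raise ValueError("no networks to average")
    labels = networks[0].labels
    for net in networks:
        if net.labels != labels:
            raise ValueError("networks must share channel labels")
    stack = np.stack([net.r_matrix for net in networks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return ConnectivityNetwork(
        band=networks[0].band,
        labels=labels,
        r_matrix=mean,
        phase_class=networks[0].phase_class,
        n_subjects=len(networks),
    )


def group_connectivity(network: ConnectivityNetwork, layout: ChannelLayout | None = None) -> dict:
    """Mean canonical correlation within each channel-pair group.

    Missing pairs are ignored; a group with no available pair yields NaN
    with a warning.
    """
    layout = layout or default_layout(network.labels)
    idx = {lab: i for i, lab in enumerate(network.labels)}
    values = {g: [] for g in PAIR_GROUPS}
    for pair, group in layout.pair_groups().items():
        l1, l2 = tuple(pair)
        if l1 not in idx or l2 not in idx:
            continue
        r = network.r_matrix[idx[l1], idx[l2]]
        if not np.isnan(r):
            values[group].append(r)
    out = {}
    for g in PAIR_GROUPS:
        if values[g]:
            out[g] = float(np.mean(values[g]))
        else:
            warnings.warn(f"no available channel pairs in group {g!r}")
            out[g] = float("nan")
    return out


# ---------------------------------------------------------------------------
# correlation baseline
# ---------------------------------------------------------------------------


def corr_connectivity(signals: dict) -> tuple:
    """Pearson-correlation connectivity of (already bandpassed) signals.

    ``signals`` maps channel labels to 1-D arrays (e.g. bandpassed oxy-Hb).
    Returns ``(labels, r_matrix)`` with NaN for zero-variance channels and on
    the diagonal.
    """
    labels = tuple(signals)
    c = len(labels)
    r = np.full((c, c), np.nan)
    arrs = [np.asarray(signals[lab], dtype=float) for lab in labels]
    for i, j in combinations(range(c), 2):
        x, y = arrs[i], arrs[j]
        if x.std() == 0 or y.std() == 0:
            continue
        r[i, j] = r[j, i] = float(np.corrcoef(x, y)[0, 1])
    return labels, r
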