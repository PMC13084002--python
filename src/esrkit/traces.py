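"""Single-cell nuclear-translocation phenotypes from time-lapse traces.

Cells carry a stress-responsive transcription factor tagged with GFP or
mCherry; upon 0.7 M NaCl addition (after frame T12) the factor transiently
relocalizes to the nucleus. Localization is summarized per frame by the
nuclear/cytoplasmic ratio: the mean of the brightest 5% of pixels of the
segmented cell divided by the median of all its pixels. From each trace we
extract the acute stress peak height (post-stress maximum of the nuclear
score over T13-T20 minus the pre-stress minimum over T11-T13), protein
abundance (mean per-frame median signal before T1-T12 or after T20-T36
stress), and AUC of the nuclear-fraction curve.

Mixed two-strain populations are demultiplexed from a constitutive nuclear
iRFP marker carried by one strain only: per-cell iRFP trace vectors are
projected on the first principal component and split by 2-means.

Cell clustering follows the Cluster 3.0 convention (uncentered correlation
distance, average linkage) on population-centered dynamics: each timepoint
column is divided by its population median, then log2-transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .phenotypes import WILCOXON_RANK_SUM, compare_groups

CHANNELS = ("GFP", "mCherry", "iRFP")

#: default frame windows (inclusive T indices)
PRE_MIN_WINDOW = (11, 13)  # pre-stress minimum for peak height
POST_MAX_WINDOW = (13, 20)  # post-stress maximum for peak height
ABUNDANCE_PRE = (1, 12)
ABUNDANCE_POST = (20, 36)


class TraceError(ValueError):
    pass


def nc_ratio(pixels) -> float:
    """Nuclear/cytoplasmic ratio of one segmented cell at one frame: mean of
    the ceil(5%) brightest pixels over the median of all pixels."""
    px = np.asarray(pixels, dtype=float).ravel()
    if px.size < 20:
        raise TraceError(f"need >= 20 pixels, got {px.size}")
    if np.any(px < 0):
        raise TraceError("pixel intensities must be nonnegative")
    med = float(np.median(px))
    if med == 0:
        raise TraceError("undefined ratio: median pixel intensity is zero")
    k = max(1, math.ceil(0.05 * px.size))
    top = np.partition(px, px.size - k)[px.size - k :]
    return float(np.mean(top)) / med


@dataclass
class CellTrace:
    """Per-cell, per-frame fluorescence summaries.

    ``frames`` are 1-based T indices; ``nuclear_fraction`` and
    ``median_signal`` map channel name to a per-frame array.
    """

    cell_id: str
    frames: np.ndarray
    nuclear_fraction: dict[str, np.ndarray] = field(default_factory=dict)
    median_signal: dict[str, np.ndarray] = field(default_factory=dict)
    strain_label: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for d in (self.nuclear_fraction, self.median_signal):
            for ch, arr in d.items():
                d[ch] = np.asarray(arr, dtype=float)
                if d[ch].shape != self.frames.shape:
                    raise TraceError(f"channel {ch} length mismatch for {self.cell_id}")

    def _window(self, lo: int, hi: int) -> np.ndarray:
        mask = (self.frames >= lo) & (self.frames <= hi)
        missing = sorted(set(range(lo, hi + 1)) - set(self.frames.tolist()))
        if missing:
            raise TraceError(f"cell {self.cell_id} missing frames {missing}")
        return mask


def peak_height(
    trace: CellTrace,
    channel: str,
    pre_window: tuple[int, int] = PRE_MIN_WINDOW,
    post_window: tuple[int, int] = POST_MAX_WINDOW,
) -> float:
    """Acute stress peak height: maximum nuclear score in the post-stress
    window minus the minimum in the immediately pre-stress window."""
    nf = trace.nuclear_fraction[channel]
    pre = nf[trace._window(*pre_window)]
    post = nf[trace._window(*post_window)]
    return float(np.max(post) - np.min(pre))


def abundance(trace: CellTrace, channel: str, window="pre") -> float:
    """Mean per-frame median signal over the pre- (T1-T12) or post-stress
    (T20-T36) window, or an explicit (lo, hi) frame pair."""
    if window == "pre":
        lo, hi = ABUNDANCE_PRE
    elif window == "post":
        lo, hi = ABUNDANCE_POST
    else:
        lo, hi = window
    mask = trace._window(lo, hi)
    return float(np.mean(trace.median_signal[channel][mask]))


def auc_nuclear(trace: CellTrace, channel: str, window: tuple[int, int]) -> float:
    """Trapezoidal area under the nuclear-fraction curve over a frame window."""
    mask = trace._window(*window)
    return float(np.trapezoid(trace.nuclear_fraction[channel][mask], trace.frames[mask]))


@dataclass(frozen=True)
class TraceMetrics:
    cell_id: str
    peak_height: float
    abundance_pre: float
    abundance_post: float
    auc_pre: float
    auc_post: float
    strain_label: str | None = None


def trace_metrics(trace: CellTrace, channel: str) -> TraceMetrics:
    return TraceMetrics(
        cell_id=trace.cell_id,
        peak_height=peak_height(trace, channel),
        abundance_pre=abundance(trace, channel, "pre"),
        abundance_post=abundance(trace, channel, "post"),
        auc_pre=auc_nuclear(trace, channel, ABUNDANCE_PRE),
        auc_post=auc_nuclear(trace, channel, ABUNDANCE_POST),
        strain_label=trace.strain_label,
    )


def demux_by_irfp(traces: list[CellTrace], *, seed: int = 0) -> tuple[list[str], float]:
    """Assign each cell to the iRFP-marked or unmarked strain.

    Per-cell iRFP median-signal vectors (all shared frames) are projected on
    the first principal component; a 2-means split on PC1 separates the
    populations and the higher-iRFP cluster is labeled ``"marked"``. Returns
    (labels, silhouette of the split).
    """
    if len(traces) < 10:
        raise TraceError(f"need >= 10 cells to demultiplex, got {len(traces)}")
    shared = set(traces[0].frames.tolist())
    for tr in traces[1:]:
        shared &= set(tr.frames.tolist())
    shared = sorted(shared)
    if not shared:
        raise TraceError("traces share no frames")
    X = np.empty((len(traces), len(shared)))
    for i, tr in enumerate(traces):
        if "iRFP" not in tr.median_signal:
            raise TraceError(f"cell {tr.cell_id} lacks an iRFP channel")
        idx = {f: j for j, f in enumerate(tr.frames.tolist())}
        X[i] = tr.median_signal["iRFP"][[idx[f] for f in shared]]
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise TraceError("cannot demultiplex: iRFP signal has no variance across cells")
    # first principal component via SVD (deterministic up to sign)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = Xc @ vt[0]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pc1[:, None])
    sizes = np.bincount(km.labels_, minlength=2)
    if sizes.min() == 0:
        raise TraceError("cannot demultiplex: degenerate 2-means split")
    means = [X[km.labels_ == c].mean() for c in (0, 1)]
    marked = int(np.argmax(means))
    labels = ["marked" if l == marked else "unmarked" for l in km.labels_]
    sil = float(silhouette_score(pc1[:, None], km.labels_))
    return labels, sil


# ---------------------------------------------------------------------------
# population-centered clustering

def center_population(matrix, mode: str = "log_ratio") -> np.ndarray:
    """Center a cells x frames nuclear-fraction matrix on the population.

    Default: divide each entry by its timepoint (column) median, then log2 —
    the blue/yellow display convention. ``mode="ratio"`` skips the log;
    ``mode="subtract"`` subtracts the column median instead.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise TraceError("need a 2-D matrix with >= 2 cells")
    med = np.median(M, axis=0)
    if mode == "subtract":
        return M - med
    if np.any(med == 0):
        raise TraceError("zero column median; cannot ratio-center")
    ratio = M / med
    if mode == "ratio":
        return ratio
    if mode == "log_ratio":
        return np.log2(ratio)
    raise TraceError(f"unknown centering mode {mode!r}")


def uncentered_correlation_distances(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Condensed pairwise 1 - uncentered-correlation distances plus a mask of
    constant (zero-norm) rows, for which the correlation is undefined."""
    M = np.asarray(M, dtype=float)
    norms = np.sqrt((M**2).sum(axis=1))
    bad = norms == 0
    safe = np.where(bad, 1.0, norms)
    U = M / safe[:, None]
    sim = np.clip(U @ U.T, -1.0, 1.0)
    D = 1.0 - sim
    # undefined distances: maximal, so flagged rows join last
    D[bad, :] = 2.0
    D[:, bad] = 2.0
    np.fill_diagonal(D, 0.0)
    return squareform(D, checks=False), bad


@dataclass
class ClusteredPopulation:
    matrix: np.ndarray  # cells x frames, population-centered
    order: np.ndarray  # leaf order (row indices)
    tree: np.ndarray  # scipy linkage matrix
    labels: list[str] | None = None
    flagged_constant: np.ndarray | None = None


def cluster_cells(centered, labels: list[str] | None = None) -> ClusteredPopulation:
    """Agglomerative hierarchical clustering of cells with uncentered
    correlation distance and average linkage (the Cluster 3.0 defaults)."""
    M = np.asarray(centered, dtype=float)
    if np.any(~np.isfinite(M)):
        raise TraceError("centered matrix contains missing values")
    dist, bad = uncentered_correlation_distances(M)
    Z = average(dist)
    order = leaves_list(Z)
    return ClusteredPopulation(
        matrix=M, order=order, tree=Z, labels=labels, flagged_constant=bad
    )


def cut_tree_k(pop: ClusteredPopulation, k: int) -> np.ndarray:
    from scipy.cluster.hierarchy import fcluster

    return fcluster(pop.tree, t=k, criterion="maxclust")


def match_abundance(
    group_a: list[TraceMetrics],
    group_b: list[TraceMetrics],
    signal_range: tuple[float, float],
    which: str = "abundance_pre",
) -> dict:
    """Subset both groups to cells with abundance inside ``signal_range`` and
    certify that the matched abundances do not differ (rank-sum p > 0.05),
    so downstream dynamics comparisons are not confounded by expression level.
    """
    lo, hi = signal_range
    sub_a = [m for m in group_a if lo <= getattr(m, which) <= hi]
    sub_b = [m for m in group_b if lo <= getattr(m, which) <= hi]
    if not sub_a or not sub_b:
        raise TraceError(
            f"empty matched subset in [{lo}, {hi}]: "
            f"{len(sub_a)}/{len(group_a)} vs {len(sub_b)}/{len(group_b)} retained"
        )
    _, p = compare_groups(
        [getattr(m, which) for m in sub_a],
        [getattr(m, which) for m in sub_b],
        mode=WILCOXON_RANK_SUM,
    )
    return {
        "matched_a": sub_a,
        "matched_b": sub_b,
        "abundance_rank_sum_p": p,
        "certified": p > 0.05,
    }


def traces_from_long(df: pd.DataFrame) -> list[CellTrace]:
    """Build traces from a long table with columns cell_id, frame, channel,
    nuclear_fraction, median_signal (one row per cell/frame/channel)."""
    out = []
    strain_col = "strain" if "strain" in df.columns else None
    for cell_id, sub in df.groupby("cell_id", sort=True):
        frames = np.sort(sub["frame"].unique())
        nf, ms = {}, {}
        for ch, chsub in sub.groupby("channel"):
            chsub = chsub.set_index("frame").reindex(frames)
            nf[ch] = chsub["nuclear_fraction"].to_numpy(dtype=float)
            ms[ch] = chsub["median_signal"].to_numpy(dtype=float)
        out.append(
            CellTrace(
                cell_id=str(cell_id),
                frames=frames,
                nuclear_fraction=nf,
                median_signal=ms,
                strain_label=str(sub[strain_col].iloc[0]) if strain_col else None,
            )
        )
    return out


def metrics_frame(traces: list[CellTrace], channel: str) -> pd.DataFrame:
    rows = [trace_metrics(t, channel).__dict__ for t in traces]
    return pd.DataFrame(rows)
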