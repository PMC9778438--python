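"""Directionality-index TAD calling.

For each bin the directionality index (DI) contrasts the contact mass to the
upstream window A against the downstream window B (default 2 Mb each side at
40 kb bins):

    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E),   E = (A + B) / 2

so DI is a signed chi-square-like statistic: strongly positive at domain
starts (downstream-biased contacts) and strongly negative at domain ends.
A 3-state Gaussian HMM segments the DI track into downstream-biased / none /
upstream-biased runs; a domain spans from the first bin of a downstream run
to the last bin of the following upstream run.  Gaps between adjacent
domains of at most 400 kb are topological boundaries, longer gaps are
unorganized chromatin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .contacts import ContactMatrix
from .genome import GenomeBins

__all__ = [
    "DiTrack",
    "DiHmm",
    "TadSet",
    "directionality_index",
    "fit_di_hmm",
    "call_tads",
    "tad_summary",
    "tss_profile",
]

BOUNDARY_MAX_GAP = 400_000  # bp; larger inter-domain gaps are "unorganized"


@dataclass
class DiTrack:
    """Per-bin directionality index over the whole genome."""

    bins: GenomeBins
    di: np.ndarray
    window: int  # bp each side
    edge: np.ndarray = field(repr=False)  # True where the window is truncated

    def chrom_di(self, chrom: str) -> np.ndarray:
        return self.di[self.bins.chrom_slice(chrom)]


@dataclass
class DiHmm:
    """Fitted 3-state DI HMM and its decoded state path.

    States are canonical after relabeling by emission mean:
    'U' (upstream-biased, lowest mean), 'N' (none), 'D' (downstream-biased,
    highest mean).
    """

    means: np.ndarray  # sorted ascending: U, N, D
    variances: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    states: np.ndarray  # '<U1' per bin: 'U' | 'N' | 'D'
    converged: bool
    model: GaussianHMM | None = field(default=None, repr=False)


@dataclass
class TadSet:
    """Ordered disjoint domains plus classified inter-domain gaps."""

    domains: pd.DataFrame  # chrom, start, end
    gaps: pd.DataFrame  # chrom, start, end, length, kind, center

    @property
    def boundaries(self) -> pd.DataFrame:
        """Boundary gap centers: DataFrame (chrom, center)."""
        b = self.gaps[self.gaps["kind"] == "boundary"]
        return b[["chrom", "center"]].reset_index(drop=True)


def _di_formula(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    e = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = (a - e) ** 2 / e + (b - e) ** 2 / e
    di = np.sign(b - a) * chi
    di[(a + b) == 0] = 0.0
    di[a == b] = 0.0
    return di


def directionality_index(
    matrices: dict[str, ContactMatrix], bins: GenomeBins, window: int = 2_000_000
) -> DiTrack:
    """Compute the DI track from per-chromosome contact matrices.

    ``window`` (bp, each side) must be a positive multiple of the bin
    resolution.  Windows are truncated at chromosome ends and the affected
    bins flagged in ``edge``.
    """
    if window < bins.resolution:
        raise ValueError(
            f"window {window} bp is smaller than the bin resolution {bins.resolution}"
        )
    w = window // bins.resolution
    di = np.zeros(bins.n_bins)
    edge = np.zeros(bins.n_bins, dtype=bool)
    for chrom, cm in matrices.items():
        v = cm.values
        n = cm.n
        cs = np.concatenate([np.zeros((n, 1)), np.cumsum(v, axis=1)], axis=1)
        idx = np.arange(n)
        lo = np.maximum(idx - w, 0)
        hi = np.minimum(idx + w, n - 1)
        a = cs[idx, idx] - cs[idx, lo]  # columns [i-w, i-1]
        b = cs[idx, hi + 1] - cs[idx, idx + 1]  # columns [i+1, i+w]
        sl = bins.chrom_slice(chrom)
        di[sl] = _di_formula(a, b)
        edge[sl] = (idx < w) | (idx > n - 1 - w)
    return DiTrack(bins, di, int(window), edge)


def fit_di_hmm(
    track: DiTrack,
    seed: int = 0,
    n_iter: int = 500,
    tol: float = 1e-4,
) -> DiHmm:
    """Fit a 3-state Gaussian HMM to the DI track and decode its state path.

    Initialization is deterministic: state means at the 10%/50%/90% DI
    quantiles, shared variance, sticky transitions.  EM runs to ``tol`` or
    ``n_iter`` iterations (non-convergence returns the best-so-far fit with a
    warning).  Decoding uses the most-probable (Viterbi) path per chromosome
    and states are relabeled canonically by emission mean.
    """
    di = track.di
    if di.size < 50:
        raise ValueError(f"need at least 50 bins to fit the DI HMM, got {di.size}")
    if np.ptp(di) == 0 or np.std(di) == 0:
        # Degenerate flat track: a single 'none' state explains everything.
        states = np.full(di.size, "N", dtype="<U1")
        m = float(di[0]) if di.size else 0.0
        return DiHmm(
            means=np.array([m, m, m]),
            variances=np.ones(3),
            transmat=np.eye(3),
            startprob=np.ones(3) / 3,
            states=states,
            converged=True,
        )

    q = np.quantile(di, [0.10, 0.50, 0.90]).astype(float)
    if not np.all(np.diff(q) > 0):
        spread = max(np.std(di), 1e-6)
        q = q + np.array([-1.0, 0.0, 1.0]) * 1e-3 * spread
    var0 = max(float(np.var(di)), 1e-8)

    model = GaussianHMM(
        n_components=3,
        covariance_type="diag",
        n_iter=n_iter,
        tol=tol,
        init_params="",
        params="stmc",
        random_state=seed,
    )
    model.startprob_ = np.ones(3) / 3
    model.transmat_ = np.full((3, 3), 0.1) + np.eye(3) * 0.7
    model.means_ = q.reshape(-1, 1)
    model.covars_ = np.full((3, 1), var0)

    lengths = [track.bins.chrom_n_bins(c) for c in track.bins.chroms]
    obs = di.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hmmlearn chatters about degenerate fits
        model.fit(obs, lengths=lengths)
    converged = bool(model.monitor_.converged)
    if not converged:
        warnings.warn("DI HMM did not converge; using best-so-far parameters")

    order = np.argsort(model.means_.ravel())
    letters = np.empty(3, dtype="<U1")
    letters[order] = ["U", "N", "D"]
    states = np.empty(di.size, dtype="<U1")
    for chrom in track.bins.chroms:
        sl = track.bins.chrom_slice(chrom)
        path = model.predict(obs[sl])
        states[sl] = letters[path]

    return DiHmm(
        means=model.means_.ravel()[order].copy(),
        variances=model.covars_.ravel()[order].copy(),
        transmat=model.transmat_.copy(),
        startprob=model.startprob_.copy(),
        states=states,
        converged=converged,
        model=model,
    )


def _scan_domains(states: np.ndarray) -> list[tuple[int, int]]:
    """Domain bin spans from a state path: first bin of a maximal 'D' run to
    the last bin of the subsequent maximal 'U' run (intervening bins of any
    state are interior)."""
    n = states.size
    domains = []
    i = 0
    while i < n:
        if states[i] == "D" and (i == 0 or states[i - 1] != "D"):
            k = i
            end = None
            while k < n:
                if states[k] == "U":
                    while k + 1 < n and states[k + 1] == "U":
                        k += 1
                    end = k
                    break
                k += 1
            if end is None:
                break  # no closing upstream run on this chromosome
            domains.append((i, end))
            i = end + 1
        else:
            i += 1
    return domains


def call_tads(
    hmm: DiHmm, bins: GenomeBins, max_boundary_gap: int = BOUNDARY_MAX_GAP
) -> TadSet:
    """Call domains from the decoded DI state path and classify the gaps.

    Inter-domain gaps of length <= ``max_boundary_gap`` (400 kb by default,
    equality counted as boundary) are topological boundaries with a single
    center coordinate at the gap midpoint; longer gaps are unorganized
    chromatin.  A chromosome with no complete down->up motif yields zero
    domains.
    """
    dom_rows = []
    gap_rows = []
    tbl = bins.table
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        states = hmm.states[sl]
        starts = tbl["start"].to_numpy()[sl]
        ends = tbl["end"].to_numpy()[sl]
        spans = _scan_domains(states)
        coords = [(int(starts[a]), int(ends[b])) for a, b in spans]
        for s, e in coords:
            dom_rows.append((chrom, s, e))
        for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
            length = s2 - e1
            kind = "boundary" if length <= max_boundary_gap else "unorganized"
            gap_rows.append((chrom, e1, s2, length, kind, (e1 + s2) // 2))
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end"])
    gaps = pd.DataFrame(
        gap_rows, columns=["chrom", "start", "end", "length", "kind", "center"]
    )
    return TadSet(domains, gaps)


def tad_summary(tads: TadSet) -> dict[str, float]:
    """Domain count, size quantiles (bp) and boundary count."""
    if tads.domains.empty:
        warnings.warn("empty TAD set")
        return {
            "count": 0,
            "median_size": 0.0,
            "mean_size": 0.0,
            "boundary_count": 0,
        }
    sizes = (tads.domains["end"] - tads.domains["start"]).to_numpy(dtype=float)
    return {
        "count": int(len(sizes)),
        "median_size": float(np.median(sizes)),
        "mean_size": float(np.mean(sizes)),
        "boundary_count": int((tads.gaps["kind"] == "boundary").sum()),
    }


def tss_profile(
    boundaries: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = 10_000,
    span_bp: int = 500_000,
) -> pd.DataFrame:
    """TSS counts in fixed windows around boundary centers.

    For offsets -span..+span in ``window_bp`` steps, counts the TSS falling
    in ``[center + offset, center + offset + window_bp)`` summed over all
    boundaries.  ``boundaries`` needs columns (chrom, center); ``tss`` needs
    (chrom, pos).  Returns a DataFrame (offset_bp, count).
    """
    offsets = np.arange(-span_bp, span_bp, window_bp, dtype=int)
    counts = np.zeros(offsets.size, dtype=int)
    for chrom, grp in boundaries.groupby("chrom"):
        positions = tss.loc[tss["chrom"] == chrom, "pos"].to_numpy()
        if positions.size == 0:
            continue
        for center in grp["center"].to_numpy():
            k = (positions - (center - span_bp)) // window_bp
            ok = (k >= 0) & (k < offsets.size)
            np.add.at(counts, k[ok].astype(int), 1)
    return pd.DataFrame({"offset_bp": offsets, "count": counts})
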