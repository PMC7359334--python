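"""Two-layered particle-state segmentation.

Layer 1 scores each 50-bp bin's (NUC, SUB110, SUB70) count vector under
three multinomial emission profiles — homogeneous nucleosome, homogeneous
subnucleosome (the two subnucleosome classes pooled), and heterogeneous
(the genome-wide baseline mixture). Layer 2 chains the bins with a hidden
Markov model whose strong self-transitions encode multi-bin domains;
parameters are refined by Baum–Welch and the genome decoded by Viterbi.
Bins with fewer than ``min_count`` fragments are NO_DATA: they are bridged
during decoding (uniform emission) but never reported as homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .fragments import COUNT_COLUMNS

STATES = ("HOM_NUC", "HOM_SUB", "HET")
NO_DATA = "NO_DATA"
DEFAULT_MIN_COUNT = 3


@dataclass
class HMMParams:
    emissions: np.ndarray     # (3 states, 3 classes), rows sum to 1
    transitions: np.ndarray   # (3, 3), rows sum to 1
    initial: np.ndarray       # (3,)

    def validate(self) -> None:
        for name, arr, axis in (("emissions", self.emissions, 1),
                                ("transitions", self.transitions, 1),
                                ("initial", self.initial, 0)):
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0) or not np.allclose(arr.sum(axis=axis), 1.0):
                raise ValueError(f"{name} rows must be probability vectors")


def default_params(genome_baseline: np.ndarray) -> HMMParams:
    """Initial parameterization: sharp nucleosome / subnucleosome emission
    profiles, HET emission = genome baseline, self-transition 0.99."""
    baseline = np.asarray(genome_baseline, dtype=float)
    baseline = baseline / baseline.sum()
    emissions = np.array([
        [0.85, 0.05, 0.10],
        [0.10, 0.20, 0.70],
        baseline,
    ])
    transitions = np.full((3, 3), 0.005)
    np.fill_diagonal(transitions, 0.99)
    return HMMParams(emissions=emissions, transitions=transitions,
                     initial=np.full(3, 1.0 / 3.0))


def _counts_matrix(track: pd.DataFrame) -> np.ndarray:
    return track[list(COUNT_COLUMNS)].to_numpy(dtype=np.int64)


def genome_baseline(track: pd.DataFrame) -> np.ndarray:
    """Genome-wide class mixture (read fractions over all bins)."""
    totals = _counts_matrix(track).sum(axis=0).astype(float)
    if totals.sum() == 0:
        raise ValueError("empty track")
    return totals / totals.sum()


def multinomial_loglik(counts: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """Exact multinomial log-likelihood of each count row under each
    emission profile; (n_bins, n_states)."""
    counts = np.asarray(counts, dtype=float)
    logp = np.log(np.clip(emissions, 1e-300, None))
    const = (gammaln(counts.sum(axis=1) + 1.0)
             - gammaln(counts + 1.0).sum(axis=1))
    return const[:, None] + counts @ logp.T


def layer1_evidence(track: pd.DataFrame, baseline: np.ndarray | None = None,
                    params: HMMParams | None = None,
                    min_count: int = DEFAULT_MIN_COUNT
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin per-state log-likelihoods and an informative-bin mask.

    Rows with total count < min_count are NO_DATA (mask False); their
    log-likelihood rows are zero so decoding bridges them neutrally.
    """
    counts = _counts_matrix(track)
    if params is None:
        if baseline is None:
            baseline = genome_baseline(track)
        params = default_params(baseline)
    ll = multinomial_loglik(counts, params.emissions)
    informative = counts.sum(axis=1) >= min_count
    ll[~informative] = 0.0
    return ll, informative


def _forward_backward(ll: np.ndarray, params: HMMParams):
    """Scaled forward-backward in log space for one chromosome."""
    n, k = ll.shape
    log_a = np.log(np.clip(params.transitions, 1e-300, None))
    alpha = np.empty((n, k))
    alpha[0] = np.log(np.clip(params.initial, 1e-300, None)) + ll[0]
    for t in range(1, n):
        alpha[t] = ll[t] + logsumexp(alpha[t - 1][:, None] + log_a, axis=0)
    loglik = float(logsumexp(alpha[-1]))
    beta = np.zeros((n, k))
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(log_a + (ll[t + 1] + beta[t + 1])[None, :], axis=1)
    gamma = np.exp(alpha + beta - loglik)
    if n > 1:
        xi = np.exp(alpha[:-1, :, None] + log_a[None]
                    + (ll[1:] + beta[1:])[:, None, :] - loglik)
        xi_sum = xi.sum(axis=0)
    else:
        xi_sum = np.zeros((k, k))
    return gamma, xi_sum, loglik


def fit_hmm(track: pd.DataFrame, init: HMMParams | None = None,
            max_iter: int = 100, tol: float = 1e-4,
            min_count: int = DEFAULT_MIN_COUNT,
            pseudocount: float = 0.5
            ) -> tuple[HMMParams, list[float]]:
    """Baum–Welch refinement of emissions, transitions and initial
    distribution.

    The emission M-step adds ``pseudocount`` to every expected class count
    so no observed class ever collapses to probability zero; this is the
    MAP update under a Dirichlet(1 + pseudocount) prior, and the returned
    ``history`` tracks the corresponding penalized log-likelihood, which
    EM makes non-decreasing iteration over iteration. Fitting stops when
    the improvement falls below ``tol`` or after ``max_iter`` evaluations;
    an infinite ``tol`` treats the first evaluation as converged and
    returns the initial parameters untouched.
    """
    if init is None:
        init = default_params(genome_baseline(track))
    init.validate()
    counts = _counts_matrix(track)
    informative = counts.sum(axis=1) >= min_count
    chrom_slices = [np.flatnonzero((track["chrom"] == c).to_numpy())
                    for c in track["chrom"].unique()]

    def log_prior(p: HMMParams) -> float:
        # Dirichlet penalty matching the M-step pseudocounts
        return (pseudocount * np.log(np.clip(p.emissions, 1e-300, None)).sum()
                + 1e-6 * np.log(np.clip(p.transitions, 1e-300, None)).sum()
                + 1e-6 * np.log(np.clip(p.initial, 1e-300, None)).sum())

    params = init
    history: list[float] = []
    for _ in range(max_iter):
        ll_all = multinomial_loglik(counts, params.emissions)
        ll_all[~informative] = 0.0
        total_ll = 0.0
        gamma_all = np.zeros((len(counts), 3))
        xi_total = np.zeros((3, 3))
        init_total = np.zeros(3)
        for idx in chrom_slices:
            gamma, xi_sum, ll = _forward_backward(ll_all[idx], params)
            total_ll += ll
            gamma_all[idx] = gamma
            xi_total += xi_sum
            init_total += gamma[0]
        history.append(total_ll + log_prior(params))
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
            break
        if np.isinf(tol):
            break
        # M-step
        em = gamma_all[informative].T @ counts[informative] + pseudocount
        em /= em.sum(axis=1, keepdims=True)
        trans = xi_total + 1e-6
        trans /= trans.sum(axis=1, keepdims=True)
        start = init_total + 1e-6
        start /= start.sum()
        params = HMMParams(emissions=em, transitions=trans, initial=start)
    return params, history


def viterbi(ll: np.ndarray, params: HMMParams) -> np.ndarray:
    """Maximum-probability state path for one chromosome's evidence."""
    n, k = ll.shape
    log_a = np.log(np.clip(params.transitions, 1e-300, None))
    delta = np.log(np.clip(params.initial, 1e-300, None)) + ll[0]
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + log_a
        back[t] = np.argmax(cand, axis=0)
        delta = ll[t] + np.max(cand, axis=0)
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def decode(track: pd.DataFrame, params: HMMParams,
           min_count: int = DEFAULT_MIN_COUNT
           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Viterbi decoding plus merged segments.

    NO_DATA bins are bridged (uniform emission) during decoding but their
    reported state is NO_DATA; segments are maximal runs of equal reported
    state.
    """
    params.validate()
    ll, informative = layer1_evidence(track, params=params, min_count=min_count)
    states = np.full(len(track), NO_DATA, dtype=object)
    for chrom in track["chrom"].unique():
        idx = np.flatnonzero((track["chrom"] == chrom).to_numpy())
        if len(idx) == 0:
            continue
        path = viterbi(ll[idx], params)
        decoded = np.array(STATES, dtype=object)[path]
        decoded[~informative[idx]] = NO_DATA
        states[idx] = decoded

    seg_rows = []
    chroms = track["chrom"].to_numpy()
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    run_start = 0
    for i in range(1, len(track) + 1):
        boundary = (i == len(track) or chroms[i] != chroms[run_start]
                    or states[i] != states[run_start])
        if boundary:
            seg_rows.append((chroms[run_start], starts[run_start],
                             ends[i - 1], states[run_start]))
            run_start = i
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"])
    return states, segments


def posterior(track: pd.DataFrame, params: HMMParams,
              min_count: int = DEFAULT_MIN_COUNT) -> np.ndarray:
    """Posterior state marginals per bin (diagnostic export)."""
    ll, _ = layer1_evidence(track, params=params, min_count=min_count)
    out = np.zeros((len(track), 3))
    for chrom in track["chrom"].unique():
        idx = np.flatnonzero((track["chrom"] == chrom).to_numpy())
        gamma, _, _ = _forward_backward(ll[idx], params)
        out[idx] = gamma
    return out


def genome_state_fractions(segments: pd.DataFrame) -> dict[str, float]:
    """Base-pair fraction per decoded state.

    The three decoded states are expressed as fractions of the assayable
    genome (they sum to 1); NO_DATA is reported separately as its fraction
    of the total segmented span.
    """
    for chrom, sub in segments.groupby("chrom"):
        sub = sub.sort_values("start")
        if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
            raise ValueError(f"overlapping segments on {chrom}")
    span = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    total = span.sum()
    by_state = {s: float(span[(segments["state"] == s).to_numpy()].sum())
                for s in (*STATES, NO_DATA)}
    assayable = sum(by_state[s] for s in STATES)
    if assayable == 0:
        raise ValueError("no assayable bases")
    out = {s: by_state[s] / assayable for s in STATES}
    out[NO_DATA] = float(by_state[NO_DATA] / total) if total else 0.0
    return out
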