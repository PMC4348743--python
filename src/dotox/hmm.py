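"""Founder-diplotype reconstruction from biallelic genotype calls.

A desk-scale hidden Markov model over the 36 unordered founder pairs
(8 homozygous + 28 heterozygous diplotypes).  Phase is not needed for dosage
regression, so unordered states halve the state space relative to ordered
pairs.  Posterior decoding (forward-backward, not Viterbi) yields expected
founder dosages — the "haplotype contribution" consumed by the genome scan,
the kinship matrix and the dominance test.

Transition model
----------------
Each haplotype independently experiences a switch event over an inter-marker
gap of ``d`` Mb with probability ``r = 1 - exp(-k * generation * d)`` where
``k = K_TRANSITION = 0.00125`` per Mb per generation; at a switch the founder
is redrawn uniformly over all 8 (the matrix-exponential solution of the
underlying Poisson switch process, so gap kernels compose exactly).  The
probability that both haplotypes escape a switch event is ``(1 - r)**2``;
the stationary distribution is uniform over ordered founder pairs, and the
mosaic simulator uses the identical process.

Emission model
--------------
A call in {A, H, B} is concordant when it equals the allele-1 copy number of
the state's two founder alleles; concordant calls emit ``1 - error_rate`` and
each of the two discordant calls emits ``error_rate / 2``.  Missing calls (N)
emit 1 for every state.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    FOUNDER_IDS,
    N_FOUNDERS,
    FounderGenomes,
    HaplotypeDosage,
)
from .synthetic import K_TRANSITION

logger = logging.getLogger(__name__)

#: canonical ordering of the 36 unordered diplotype states
DIPLOTYPE_STATES: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(N_FOUNDERS) for j in range(i, N_FOUNDERS)
)
N_STATES = len(DIPLOTYPE_STATES)  # 36

#: (36, 8) matrix: copies of each founder carried by each state
STATE_FOUNDER_COUNTS = np.zeros((N_STATES, N_FOUNDERS))
for _s, (_i, _j) in enumerate(DIPLOTYPE_STATES):
    STATE_FOUNDER_COUNTS[_s, _i] += 1
    STATE_FOUNDER_COUNTS[_s, _j] += 1

# ordered (i, j) -> unordered state index
_ORDERED_TO_STATE = np.zeros((N_FOUNDERS, N_FOUNDERS), dtype=int)
for _s, (_i, _j) in enumerate(DIPLOTYPE_STATES):
    _ORDERED_TO_STATE[_i, _j] = _s
    _ORDERED_TO_STATE[_j, _i] = _s

_CALL_CODE = {"A": 0, "H": 1, "B": 2, "N": 3}

#: stationary distribution over unordered diplotypes (uniform over ordered
#: pairs: 1/64 per homozygous state, 2/64 per heterozygous state)
STATIONARY_36 = np.array(
    [1.0 / 64 if i == j else 2.0 / 64 for (i, j) in DIPLOTYPE_STATES]
)


def per_haplotype_transition(r: float) -> np.ndarray:
    """8x8 single-haplotype transition ``(1 - r) I + (r / 8) J``: no switch
    event with probability 1 - r, otherwise the founder is redrawn uniformly
    over all 8 (so P(retain both haplotypes) = (1 - r)**2 refers to the
    switch events, and the kernel composes consistently across gaps)."""
    P = np.full((N_FOUNDERS, N_FOUNDERS), r / N_FOUNDERS)
    np.fill_diagonal(P, 1.0 - r + r / N_FOUNDERS)
    return P


def switch_probability(distance_mb: float, generation: int) -> float:
    """Per-haplotype founder-switch probability over an inter-marker gap."""
    if distance_mb < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 - np.exp(-K_TRANSITION * generation * distance_mb)


def transition_matrix(distance_mb: float, generation: int) -> np.ndarray:
    """36x36 stochastic matrix over unordered diplotype states.

    Built by lumping the 64-state ordered-pair chain (the product of two
    independent single-haplotype chains); the ordered chain is lumpable onto
    unordered pairs because the per-haplotype kernel is symmetric.
    """
    r = switch_probability(distance_mb, generation)
    P = per_haplotype_transition(r)
    T64 = np.kron(P, P)  # ordered (i1, i2) -> (j1, j2), index = i1 * 8 + i2
    T36 = np.zeros((N_STATES, N_STATES))
    for s, (i, j) in enumerate(DIPLOTYPE_STATES):
        row = T64[i * N_FOUNDERS + j]  # any ordered representative
        for o in range(N_FOUNDERS * N_FOUNDERS):
            T36[s, _ORDERED_TO_STATE[o // N_FOUNDERS, o % N_FOUNDERS]] += row[o]
    return T36


def emission_prob(
    call: str,
    diplotype: tuple[int, int],
    founder_alleles_at_marker: np.ndarray,
    error_rate: float,
) -> float:
    """P(observed call | diplotype state) at a single marker."""
    if call not in _CALL_CODE:
        raise ValueError(f"unknown call symbol {call!r}")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    if call == "N":
        return 1.0
    i, j = diplotype
    expected = int(founder_alleles_at_marker[i]) + int(founder_alleles_at_marker[j])
    return 1.0 - error_rate if _CALL_CODE[call] == expected else error_rate / 2.0


def _emission_table(alleles: np.ndarray, error_rate: float) -> np.ndarray:
    """(n_markers, 4, 36) lookup of emission probs per marker, call code, state."""
    m = alleles.shape[0]
    idx_i = np.array([i for i, _ in DIPLOTYPE_STATES])
    idx_j = np.array([j for _, j in DIPLOTYPE_STATES])
    expected = alleles[:, idx_i] + alleles[:, idx_j]  # (m, 36) in {0,1,2}
    E = np.full((m, 4, N_STATES), error_rate / 2.0)
    for code in range(3):
        E[:, code, :][expected == code] = 1.0 - error_rate
    E[:, 3, :] = 1.0  # N emits 1
    return E


def _forward_backward(
    calls: np.ndarray, E: np.ndarray, transitions: list[np.ndarray]
) -> np.ndarray:
    """Scaled forward-backward for many mice at once on one chromosome.

    calls: (n_markers, n_mice) integer call codes; E: (n_markers, 4, 36);
    transitions: list of (36, 36), one per inter-marker gap.
    Returns posteriors of shape (n_mice, n_markers, 36).
    """
    m, n = calls.shape
    post = np.empty((n, m, N_STATES))
    # emissions per marker per mouse: (m, n, 36)
    em = E[np.arange(m)[:, None], calls, :]

    alpha = np.empty((m, n, N_STATES))
    scale = np.empty((m, n))
    a = em[0] * STATIONARY_36
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for t in range(1, m):
        a = (alpha[t - 1] @ transitions[t - 1]) * em[t]
        scale[t] = a.sum(axis=1)
        # guard against an all-zero row (pathological emissions)
        scale[t][scale[t] == 0] = 1.0
        alpha[t] = a / scale[t][:, None]

    beta = np.ones((n, N_STATES))
    post[:, m - 1] = alpha[m - 1] * beta
    for t in range(m - 2, -1, -1):
        beta = (beta * em[t + 1]) @ transitions[t].T
        beta /= scale[t + 1][:, None]
        post[:, t] = alpha[t] * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def reconstruct(
    genotypes: pd.DataFrame,
    founders: FounderGenomes,
    generation: int = 8,
    error_rate: float = 0.002,
    return_posteriors: bool = False,
):
    """Posterior founder dosages for every mouse from genotype calls.

    ``genotypes`` is the markers x mice call table (values A/H/B/N, index =
    marker ids matching the founder map).  Returns a :class:`HaplotypeDosage`
    (and, optionally, a dict chromosome -> posterior array of shape
    (n_mice, n_markers_on_chr, 36)).
    """
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    mmap = founders.marker_map
    markers = mmap["marker"].to_numpy()
    missing = [m for m in markers if m not in genotypes.index]
    if missing:
        raise KeyError(f"genotypes missing markers: {missing[:5]}")
    calls_all = genotypes.loc[markers].to_numpy()
    codes_all = np.vectorize(_CALL_CODE.__getitem__)(calls_all)
    mice = list(genotypes.columns)

    E_all = _emission_table(founders.alleles, error_rate)
    dosages = np.empty((len(mice), len(markers), N_FOUNDERS))
    posteriors: dict = {}
    for chrom in founders.chromosomes:
        idx = np.flatnonzero((mmap["chr"] == chrom).to_numpy())
        pos = mmap["pos_Mb"].to_numpy(float)[idx]
        gaps = np.diff(pos)
        transitions = [transition_matrix(d, generation) for d in gaps]
        codes = codes_all[idx]
        all_missing = np.flatnonzero((codes == 3).all(axis=0))
        if all_missing.size:
            logger.warning(
                "chr %s: %d mice with no calls; posteriors are uniform there",
                chrom,
                all_missing.size,
            )
        post = _forward_backward(codes, E_all[idx], transitions)
        dosages[:, idx, :] = post @ STATE_FOUNDER_COUNTS
        if return_posteriors:
            posteriors[chrom] = post

    out = HaplotypeDosage(mice, mmap, dosages)
    out.validate(atol=1e-6)
    if return_posteriors:
        return out, posteriors
    return out


def reconstruction_accuracy(
    truth: HaplotypeDosage, estimate: HaplotypeDosage
) -> float:
    """Mean over mice and markers of the dosage overlap
    ``0.5 * sum_f min(true_f, est_f)``; 1 for a perfect reconstruction, 0 for
    disjoint founder content."""
    if truth.dosages.shape != estimate.dosages.shape:
        raise ValueError("truth and estimate must cover the same mice and markers")
    if not np.array_equal(
        truth.marker_map["marker"].to_numpy(), estimate.marker_map["marker"].to_numpy()
    ):
        raise ValueError("marker sets differ between truth and estimate")
    overlap = 0.5 * np.minimum(truth.dosages, estimate.dosages).sum(axis=2)
    return float(overlap.mean())
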