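"""Stage two: EM clustering of denoised sequences under a PCR error model.

PCR introduces single-base substitutions at rates that depend on the
nucleotides involved (transitions A<->G and C<->T are an order of magnitude
more frequent than transversions, the classic Taq signature).  The distance
between a read r and a hypothesised true sequence S is the mean per-column
-log transition probability over their global alignment, gap penalties
included:

    e(r, S) = [ sum_l -log P(r_l | s_l) + gap penalties ] / A

with A the number of alignment columns.  Alignment uses the homopolymer-aware
Needleman-Wunsch (a cheap gap for run extension/contraction catches residual
flow noise on rare reads).  Clustering then reuses the shared exponential-
kernel EM with the stage-one abundances as read weights, so frequency
information propagates into the mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .align import Alignment, align
from .em import MixtureState, init_complete_linkage, run_em

__all__ = [
    "TransitionModel",
    "WeightedSequence",
    "align_homopolymer_nw",
    "seq_distance",
    "pairwise_distances",
    "SeqnoiseResult",
    "run_seqnoise",
]

DEFAULT_SIGMA_S = 0.033  # GS FLX; 0.1 and 0.04 are the documented Titanium presets
DEFAULT_CUT_S = 0.08
DEFAULT_GAP = 15.0
DEFAULT_HGAP = 4.0

# Measured PCR substitution probabilities P(observed m | true n), A/C/G/T order,
# with the per-base total error frequency f and the per-cycle rate p per
# template base.  Rows are renormalized at load to remove rounding drift.
_DEFAULT_SUB = np.array(
    [
        # A        C        G        T
        [0.9995, 7.2e-6, 5.1e-4, 7.7e-6],  # A
        [1.1e-5, 0.9996, 2.1e-6, 4.1e-4],  # C
        [3.5e-4, 3.2e-6, 0.9996, 2.1e-5],  # G
        [9.0e-6, 5.7e-4, 1.4e-5, 0.9994],  # T
    ]
)
_DEFAULT_TOTAL_F = {"A": 5.2e-4, "C": 4.2e-4, "G": 3.7e-4, "T": 5.9e-4}
_DEFAULT_PER_CYCLE = {"A": 3.5e-5, "C": 2.8e-5, "G": 2.5e-5, "T": 4.0e-5}
PCR_CYCLES = 30

_BASES = "ACGT"


def per_cycle_rate(total_f: float, cycles: int = PCR_CYCLES) -> float:
    """Per-cycle error rate from a whole-run error frequency.

    Under ideal doubling a molecule sampled after c cycles has been newly
    synthesised in Binomial(c, 1/2) of them, so the accumulated per-base error
    frequency is f = p * c / 2 and p = 2 f / c.
    """
    return 2.0 * total_f / cycles


@dataclass
class TransitionModel:
    """4x4 PCR substitution costs plus the two gap penalties.

    ``sub_neg_log[n, m] = -log P(m | n)`` in A/C/G/T order.  The diagonal cost
    is small but non-zero and is *not* zeroed: identity columns carry the
    probability of no error, exactly as the distance defines it.
    """

    sub_neg_log: np.ndarray
    gap_penalty: float = DEFAULT_GAP
    homopolymer_gap_penalty: float = DEFAULT_HGAP
    total_f: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TOTAL_F))
    per_cycle: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PER_CYCLE))

    def __post_init__(self) -> None:
        self.sub_neg_log = np.asarray(self.sub_neg_log, dtype=float)
        if self.sub_neg_log.shape != (4, 4):
            raise ValueError("substitution table must be 4x4")
        if self.gap_penalty <= 0 or self.homopolymer_gap_penalty <= 0:
            raise ValueError("gap penalties must be positive")

    @classmethod
    def default(cls) -> "TransitionModel":
        return cls.from_probs(_DEFAULT_SUB)

    @classmethod
    def from_probs(cls, probs: np.ndarray, **kwargs) -> "TransitionModel":
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum(axis=1, keepdims=True)  # remove rounding drift
        return cls(sub_neg_log=-np.log(probs), **kwargs)

    def probs(self) -> np.ndarray:
        return np.exp(-self.sub_neg_log)

    def save(self, path: str | Path) -> None:
        """Editable TSV: header row/cols A C G T, probabilities."""
        p = self.probs()
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(_BASES) + "\n")
            for i, b in enumerate(_BASES):
                fh.write(b + "\t" + "\t".join(f"{v:.6e}" for v in p[i]) + "\n")

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "TransitionModel":
        rows = []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header != list(_BASES):
                raise ValueError("transition TSV must have A C G T columns")
            for line in fh:
                parts = line.strip().split("\t")
                rows.append([float(v) for v in parts[1:]])
        return cls.from_probs(np.array(rows), **kwargs)


@dataclass
class WeightedSequence:
    id: str
    seq: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        self.seq = self.seq.upper()


def align_homopolymer_nw(a: str, b: str, tm: TransitionModel) -> Alignment:
    """Global alignment of ``a`` (the noisy read) against ``b`` under ``tm``.

    A match/mismatch column (observed m over true n) costs ``-log P(m|n)``;
    the first argument is always the noisy read, the second the hypothesis,
    which matters whenever the substitution table is asymmetric.
    """
    return align(
        a,
        b,
        sub=tm.sub_neg_log.T,  # align() indexes [read base, hypothesis base]
        gap=tm.gap_penalty,
        hgap=tm.homopolymer_gap_penalty,
        homopolymer_aware=True,
    )


def seq_distance(r: str, s: str, tm: TransitionModel) -> float:
    """e(r, S): alignment cost normalised by alignment length (all columns)."""
    aln = align_homopolymer_nw(r, s, tm)
    return aln.cost / aln.n_columns


def pairwise_distances(
    reads: list[str], refs: list[str], tm: TransitionModel, n_jobs: int = 1
) -> np.ndarray:
    """e(read i, ref k) matrix; rows may be computed in parallel workers.

    Worker results are assembled in row order, so the matrix is bit-identical
    to a serial run regardless of ``n_jobs``.
    """

    def row(r: str) -> np.ndarray:
        return np.array([seq_distance(r, s, tm) for s in refs])

    if n_jobs == 1:
        rows = [row(r) for r in reads]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(row)(r) for r in reads)
    return np.stack(rows)


@dataclass
class SeqnoiseResult:
    sequences: list[WeightedSequence]  # denoised, frequency = summed input weight
    mapping: dict[str, int]  # input id -> index into sequences
    state: MixtureState


def run_seqnoise(
    seqs: list[WeightedSequence],
    tm: TransitionModel | None = None,
    sigma_s: float = DEFAULT_SIGMA_S,
    cut_s: float = DEFAULT_CUT_S,
    truncate_len: int = 220,
    max_iter: int = 1000,
    tol: float = 1e-6,
    n_jobs: int = 1,
) -> SeqnoiseResult:
    """Cluster abundance-weighted sequences into true sequences.

    Sequences are truncated to ``truncate_len`` (220 bp GS FLX / 400 bp
    Titanium, where end-of-read error rates climb), de-duplicated with weights
    summed, and clustered by EM with candidates restricted to the observed
    unique sequences.  Output frequencies are the summed input weights of the
    reads mapping to each component, so total weight is conserved exactly.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if tm is None:
        tm = TransitionModel.default()

    truncated: dict[str, float] = {}
    first_id: dict[str, str] = {}
    for ws in seqs:
        t = ws.seq[:truncate_len]
        truncated[t] = truncated.get(t, 0.0) + ws.weight
        first_id.setdefault(t, ws.id)
    # candidate order: abundance descending, then lexicographic
    uniq = sorted(truncated, key=lambda s: (-truncated[s], s))
    weights = np.array([truncated[s] for s in uniq])

    C = pairwise_distances(uniq, uniq, tm, n_jobs=n_jobs)
    sym = 0.5 * (C + C.T)
    np.fill_diagonal(sym, 0.0)
    labels = init_complete_linkage(sym, cut_s)
    state = run_em(C, labels, sigma=sigma_s, weights=weights, max_iter=max_iter, tol=tol)

    assign = state.hard_assignments()
    win_cand = state.candidate_idx[assign]  # per unique seq, winning candidate
    out_freq: dict[int, float] = {}
    for i, cand in enumerate(win_cand):
        out_freq[int(cand)] = out_freq.get(int(cand), 0.0) + weights[i]
    order = sorted(out_freq, key=lambda c: (-out_freq[c], uniq[c]))
    cand_to_out = {c: k for k, c in enumerate(order)}
    sequences = [
        WeightedSequence(id=first_id[uniq[c]], seq=uniq[c], weight=out_freq[c]) for c in order
    ]
    # map every input id through its truncated form
    trunc_index = {s: i for i, s in enumerate(uniq)}
    mapping = {
        ws.id: cand_to_out[int(win_cand[trunc_index[ws.seq[:truncate_len]]])] for ws in seqs
    }
    return SeqnoiseResult(sequences=sequences, mapping=mapping, state=state)
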