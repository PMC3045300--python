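"""Abundance-aware de novo chimera detection (parent search, chimera index,
logistic classification).

A PCR chimera is spliced from two templates at a discrete breakpoint during
an incomplete-extension cycle, so both parents experience at least one more
PCR round than the chimera and are present with equal or greater abundance.
For each query sequence the search therefore runs only over heavier
sequences: pairwise alignments to every possible parent give per-position
prefix/suffix cost arrays, and the best (prefix parent, suffix parent,
breakpoint) triple falls out of independent minima per side — no explicit
pair enumeration.

A plausible reconstruction (distance < 0.15 and no worse than the closest
single parent) is then scored by the *chimera index* I: under the null that
the query is an ordinary diverged sequence, base changes on the branch to
each parent (from the three-way parsimony ancestor) would scatter
binomially across the two alignment parts in proportion to part size.  I is
the negative log of the joint probability of a split at least as biased as
observed, and a one-dimensional logistic regression on I turns it into a
probability of being chimeric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import binom

from .align import Alignment, prefix_costs
from .seqnoise import TransitionModel, WeightedSequence, align_homopolymer_nw

__all__ = [
    "ChimeraCandidate",
    "LogisticModel",
    "find_best_parents",
    "parsimony_change_counts",
    "chimera_index",
    "logistic_predict",
    "logistic_train",
    "run_perseus",
]

DEFAULT_ALPHA = -7.5
DEFAULT_BETA = 0.5
DEFAULT_DIST_THRESHOLD = 0.15


@dataclass
class LogisticModel:
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    @property
    def decision_point(self) -> float:
        """The index value classified chimeric with exactly 50% probability."""
        if self.beta == 0:
            raise ValueError("decision point undefined for beta = 0")
        return -self.alpha / self.beta


@dataclass
class ChimeraCandidate:
    query_id: str
    parent_a: str | None  # closest parent
    parent_b: str | None  # more distant parent
    breakpoint: int | None  # query (ungapped) coordinate, half-open split
    dist_chimera: float
    dist_parent: float
    changes: tuple[int, int, int, int, int, int] | None  # x_A,x_B,y_A,y_B,z_A,z_B
    index: float
    prob: float
    call: str  # "chimeric" or "good"


def _projected_row(aln: Alignment) -> str:
    """Parent row of a pairwise alignment projected onto query coordinates.

    One character per query base: the aligned parent base, or '-' where the
    parent is gapped; parent insertions (query-gap columns) are dropped, so
    three-way alignments built from two projections share coordinates.
    """
    return "".join(cb for ca, cb in zip(aln.a_aligned, aln.b_aligned) if ca != "-")


def _parent_profiles(query: str, parents: list[WeightedSequence], tm: TransitionModel):
    """Per-parent suffix/prefix cost arrays and full-alignment distance.

    ``fwd[i]`` is the optimal cost of aligning ``query[:i]`` against any
    prefix of the parent (forward DP row minima); ``rev[i]`` the optimal cost
    of ``query[i:]`` against any parent suffix (reverse DP).  A spliced
    reconstruction with breakpoint i from prefix parent P and suffix parent S
    then costs exactly ``fwd_P[i] + rev_S[i]``.
    """
    profiles = []
    for p in parents:
        aln = align_homopolymer_nw(query, p.seq, tm)
        fwd = prefix_costs(
            query, p.seq, tm.sub_neg_log.T, tm.gap_penalty, tm.homopolymer_gap_penalty
        )
        rev = prefix_costs(
            query[::-1], p.seq[::-1], tm.sub_neg_log.T, tm.gap_penalty,
            tm.homopolymer_gap_penalty,
        )[::-1]
        profiles.append(
            {
                "parent": p,
                "fwd": fwd,
                "rev": rev,
                "projected": _projected_row(aln),
                "e": aln.cost / aln.n_columns,
            }
        )
    return profiles


def _best_splice(profiles) -> tuple[float, int, int, int]:
    """Minimum spliced cost over (prefix parent, suffix parent, breakpoint).

    The minimum over parent pairs separates per side, so only the per-side
    minima are scanned.  Ties resolve to the lowest (breakpoint, prefix
    index, suffix index), matching the exhaustive pair enumeration.
    """
    left = np.stack([p["fwd"] for p in profiles])  # K x (n+1)
    right = np.stack([p["rev"] for p in profiles])
    li = np.argmin(left, axis=0)
    ri = np.argmin(right, axis=0)
    cols = np.arange(left.shape[1])
    totals = left[li, cols] + right[ri, cols]
    bp = int(np.argmin(totals))
    return float(totals[bp]), bp, int(li[bp]), int(ri[bp])


def find_best_parents(
    query: WeightedSequence,
    pool: list[WeightedSequence],
    tm: TransitionModel,
) -> tuple[str, str, int, float, float] | None:
    """Best chimeric reconstruction of ``query`` from heavier pool members.

    Returns (parent_a, parent_b, breakpoint, dist_chimera, dist_parent) with
    parent_a the closer parent by full-alignment distance, or ``None`` when no
    pool member has weight >= the query's (the query is most abundant).
    Breakpoints are query ungapped coordinates; ``dist_chimera`` is the
    spliced cost normalised by the query length.
    """
    parents = sorted(
        (p for p in pool if p.weight >= query.weight and p.id != query.id),
        key=lambda p: (-p.weight, p.id),
    )
    if not parents:
        return None
    profiles = _parent_profiles(query.seq, parents, tm)
    dist_parent = min(p["e"] for p in profiles)
    cost, bp, li, ri = _best_splice(profiles)
    dist_chimera = cost / len(query.seq)  # normalised per query position
    prefix, suffix = profiles[li], profiles[ri]
    if prefix["e"] <= suffix["e"]:
        a, b = prefix["parent"].id, suffix["parent"].id
    else:
        a, b = suffix["parent"].id, prefix["parent"].id
    return a, b, bp, float(dist_chimera), float(dist_parent)


def parsimony_change_counts(
    row_a: str, row_b: str, row_c: str, breakpoint: int, a_is_prefix: bool = True
) -> tuple[int, int, int, int, int, int]:
    """Per-branch change counts from a three-row alignment, split at the break.

    The ancestral state per column is the majority of the three characters
    (gaps count as a state); each row differing from the ancestor scores one
    change on its branch.  Columns with three distinct states attribute no
    change (the Fitch ancestor is ambiguous).  Counts are partitioned into the
    part of the alignment matching parent A and the part matching parent B;
    with ``a_is_prefix`` the A part is columns ``[0, breakpoint)``.

    Returns (x_A, x_B, y_A, y_B, z_A, z_B): changes on the branches to the
    close parent A (x), distant parent B (y) and the query C (z).
    """
    if not (len(row_a) == len(row_b) == len(row_c)):
        raise ValueError("alignment rows must have equal length")
    if not 0 <= breakpoint <= len(row_a):
        raise ValueError("breakpoint outside the alignment")
    counts = np.zeros((3, 2), dtype=np.int64)  # rows: A,B,C; cols: part A, part B
    for col, (ca, cb, cc) in enumerate(zip(row_a, row_b, row_c)):
        states = (ca, cb, cc)
        if len(set(states)) == 3:
            continue
        # majority state
        anc = max(set(states), key=states.count)
        in_left = col < breakpoint
        part = 0 if (in_left == a_is_prefix) else 1
        for branch, s in enumerate(states):
            if s != anc:
                counts[branch, part] += 1
    return (
        int(counts[0, 0]),
        int(counts[0, 1]),
        int(counts[1, 0]),
        int(counts[1, 1]),
        int(counts[2, 0]),
        int(counts[2, 1]),
    )


def chimera_index(
    changes: tuple[int, int, int, int, int, int], len_a: int, len_b: int
) -> float:
    """Negative log joint binomial tail probability of the observed change split.

    ``p_B = Pr[Bin(y, len_a/(len_a+len_b)) >= y_A]`` — how unlikely it is that
    changes to the *distant* parent concentrate in the part matching the close
    parent at least as much as observed; symmetrically ``p_A`` for changes to
    the close parent landing in the distant part.  ``I = -ln(p_B * p_A)``;
    empty change sets give tail probability 1 and contribute nothing.
    """
    if len_a < 1 or len_b < 1:
        raise ValueError("both alignment parts must be non-empty")
    x_a, x_b, y_a, y_b, _, _ = changes
    x, y = x_a + x_b, y_a + y_b
    frac_a = len_a / (len_a + len_b)
    p_b = float(binom.sf(y_a - 1, y, frac_a)) if y > 0 else 1.0
    p_a = float(binom.sf(x_b - 1, x, 1.0 - frac_a)) if x > 0 else 1.0
    return float(-np.log(p_b * p_a))


def logistic_predict(index: float, model: LogisticModel) -> float:
    """P(chimeric | I) = 1 / (1 + exp(-(alpha + beta I)))."""
    return float(1.0 / (1.0 + np.exp(-(model.alpha + model.beta * index))))


def logistic_train(
    samples: list[tuple[float, bool]], maxiter: int = 25
) -> tuple[LogisticModel, dict]:
    """Maximum-likelihood one-dimensional logistic regression on the index.

    Fit by IRLS (binomial GLM).  On completely separated training data the
    iteration hits ``maxiter`` without converging; the returned coefficients
    still define a finite separating decision point, which is reported along
    with a non-convergence flag, so the P50 rule remains usable.  Diagnostics
    carry the null/residual deviances and the decision point.
    """
    if len(samples) < 2:
        raise ValueError("need at least two training samples")
    idx = np.array([s[0] for s in samples], dtype=float)
    lab = np.array([1.0 if s[1] else 0.0 for s in samples])
    if lab.min() == lab.max():
        raise ValueError("training data must contain both classes")
    X = sm.add_constant(idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(lab, X, family=sm.families.Binomial()).fit(maxiter=maxiter)
    alpha, beta = float(res.params[0]), float(res.params[1])
    model = LogisticModel(alpha=alpha, beta=beta)
    # a residual deviance of ~0 means the classes are perfectly separated:
    # the likelihood has no maximum and the coefficients run off to infinity,
    # but the decision point they define is still the separating line
    separated = float(res.deviance) < 1e-6
    diagnostics = {
        "converged": bool(res.converged) and not separated,
        "separated": separated,
        "null_deviance": float(res.null_deviance),
        "deviance": float(res.deviance),
        "standard_errors": [float(v) for v in res.bse],
        "decision_point": model.decision_point if beta != 0 else np.nan,
    }
    if beta < 0:
        warnings.warn("fitted beta < 0: the index decreases chimera probability")
    if not res.converged:
        warnings.warn(
            "logistic fit did not converge (training data may be perfectly "
            f"separated); decision point {diagnostics['decision_point']:.3f}"
        )
    return model, diagnostics


def _three_way(
    query: str, profiles, li: int, ri: int
) -> tuple[str, str, str]:
    """Three-row alignment (prefix parent, suffix parent, query) on query
    coordinates; parent deletions show as gaps, parent insertions are dropped."""
    return profiles[li]["projected"], profiles[ri]["projected"], query


def run_perseus(
    seqs: list[WeightedSequence],
    tm: TransitionModel | None = None,
    model: LogisticModel | None = None,
    dist_threshold: float = DEFAULT_DIST_THRESHOLD,
) -> list[ChimeraCandidate]:
    """Score every sequence for being a PCR chimera of heavier sequences.

    Sequences are processed in decreasing abundance (ties in id order).  A
    sequence is a chimera *candidate* only if its best reconstruction lies
    strictly closer than ``dist_threshold`` and no further than the closest
    single possible parent; candidates get an index and a logistic
    probability, everything else gets probability 0.  ``call`` is
    ``"chimeric"`` iff the probability exceeds 0.5.
    """
    if tm is None:
        tm = TransitionModel.default()
    if model is None:
        model = LogisticModel()
    ordered = sorted(seqs, key=lambda s: (-s.weight, s.id))
    out: list[ChimeraCandidate] = []
    for query in ordered:
        pool = [s for s in ordered if s.id != query.id]
        parents = [p for p in pool if p.weight >= query.weight]
        if not parents:
            out.append(
                ChimeraCandidate(query.id, None, None, None, np.inf, np.inf, None, 0.0, 0.0, "good")
            )
            continue
        profiles = _parent_profiles(query.seq, parents, tm)
        dist_parent = min(p["e"] for p in profiles)
        cost, bp, li, ri = _best_splice(profiles)
        dist_chimera = float(cost / len(query.seq))
        prefix_closer = profiles[li]["e"] <= profiles[ri]["e"]
        a_id = profiles[li]["parent"].id if prefix_closer else profiles[ri]["parent"].id
        b_id = profiles[ri]["parent"].id if prefix_closer else profiles[li]["parent"].id
        if dist_chimera < dist_threshold and dist_chimera <= dist_parent:
            row_pre, row_suf, row_c = _three_way(query.seq, profiles, li, ri)
            if prefix_closer:
                changes = parsimony_change_counts(row_pre, row_suf, row_c, bp, a_is_prefix=True)
            else:
                changes = parsimony_change_counts(row_suf, row_pre, row_c, bp, a_is_prefix=False)
            len_a = bp if prefix_closer else len(query.seq) - bp
            len_b = len(query.seq) - len_a
            if len_a >= 1 and len_b >= 1:
                index = chimera_index(changes, len_a, len_b)
            else:
                index = 0.0
            prob = logistic_predict(index, model)
        else:
            changes, index, prob = None, 0.0, 0.0
        out.append(
            ChimeraCandidate(
                query_id=query.id,
                parent_a=a_id,
                parent_b=b_id,
                breakpoint=bp,
                dist_chimera=dist_chimera,
                dist_parent=float(dist_parent),
                changes=changes,
                index=float(index),
                prob=float(prob),
                call="chimeric" if prob > 0.5 else "good",
            )
        )
    return out


def report_frame(candidates: list[ChimeraCandidate]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": c.query_id,
                "parent_a": c.parent_a,
                "parent_b": c.parent_b,
                "breakpoint": c.breakpoint,
                "dist_chimera": c.dist_chimera,
                "dist_parent": c.dist_parent,
                "index": c.index,
                "prob": c.prob,
                "call": c.call,
            }
            for c in candidates
        ]
    )
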