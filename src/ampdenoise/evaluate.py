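"""Assessment machinery: per-base error rates, reference-based chimera
labelling, and OTU construction accuracy.

These are the yardsticks for denoising on data of known composition: how many
residual differences per base remain against the true templates, which
denoised sequences are explainable as splices of references (bimera/trimera/
quadramera), and whether clustering the output yields the OTUs the reference
set defines — counted as Good (reference + denoised members), Missed
(reference only) and Noise (denoised only).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _linkage
from scipy.spatial.distance import squareform

from .align import align, unit_cost_matrix
from .seqnoise import TransitionModel, align_homopolymer_nw

__all__ = [
    "ReferenceLabel",
    "OTUPartition",
    "per_base_error_rate",
    "classify_vs_reference",
    "percent_difference_matrix",
    "cluster_otus",
    "otu_accuracy",
]


class ChimeraClass(str, Enum):
    GOOD = "Good"
    BIMERA = "Bimera"
    TRIMERA = "Trimera"
    QUADRAMERA = "Quadramera"
    UNCLASSIFIED = "Unclassified"


@dataclass
class ReferenceLabel:
    label: ChimeraClass
    best_distance: float
    improvement_chain: list[int]  # nucleotide improvements at 1, 2, 3 breakpoints


# ---------------------------------------------------------------------------
# per-base error rate


def _closest_ref(seq: str, refs: list[str], tm: TransitionModel) -> int:
    best, best_diffs = 0, None
    for k, ref in enumerate(refs):
        d = align_homopolymer_nw(seq, ref, tm).differences()
        if best_diffs is None or d < best_diffs:
            best, best_diffs = k, d
    return best


def per_base_error_rate(
    reads: list[str],
    refs: list[str],
    tm: TransitionModel | None = None,
    mapped: list[str] | None = None,
) -> float:
    """Percentage of erroneous bases across a data set.

    Each read is matched to its closest reference; the differences between
    the scored sequence and that reference are summed and divided by the
    summed alignment lengths (x100).  For denoised data pass ``mapped``: read
    i is then scored as the denoised sequence it maps to, but still against
    the closest reference of the *original* read — so misassignment by the
    denoiser counts as error rather than hiding it.
    """
    if not refs:
        raise ValueError("need at least one reference")
    if tm is None:
        tm = TransitionModel.default()
    total_diffs = 0
    total_cols = 0
    # identical read sequences recur constantly; cache per unique sequence
    ref_cache: dict[str, int] = {}
    pair_cache: dict[tuple[str, int], tuple[int, int]] = {}
    for i, read in enumerate(reads):
        if read not in ref_cache:
            ref_cache[read] = _closest_ref(read, refs, tm)
        k = ref_cache[read]
        scored = read if mapped is None else mapped[i]
        key = (scored, k)
        if key not in pair_cache:
            aln = align_homopolymer_nw(scored, refs[k], tm)
            pair_cache[key] = (aln.differences(), aln.n_columns)
        d, c = pair_cache[key]
        total_diffs += d
        total_cols += c
    return 100.0 * total_diffs / total_cols


# ---------------------------------------------------------------------------
# reference-based chimera labelling


def _ref_profiles(seq: str, refs: list[str], tm: TransitionModel):
    """Per-reference prefix arrays of differences and model cost over the
    query's ungapped coordinates (reference-only columns attach leftward)."""
    n = len(seq)
    diffs = np.zeros((len(refs), n + 1))
    costs = np.zeros((len(refs), n + 1))
    for r, ref in enumerate(refs):
        aln = align_homopolymer_nw(seq, ref, tm)
        cum_d, cum_c, i = 0, 0.0, 0
        for ca, cb, cc in zip(aln.a_aligned, aln.b_aligned, aln.column_costs):
            if ca != "-":
                diffs[r, i] = cum_d
                costs[r, i] = cum_c
                i += 1
            cum_d += 1 if ca != cb else 0
            cum_c += cc
        diffs[r, n] = cum_d
        costs[r, n] = cum_c
    return diffs, costs


def _multi_breakpoint_best(prefix: np.ndarray, max_segments: int) -> np.ndarray:
    """Minimum total over reconstructions with 1..max_segments segments.

    ``prefix`` is R x (n+1); segment [j, i) from reference r costs
    ``prefix[r, i] - prefix[r, j]`` (costs along each pairwise alignment
    path).  Dynamic programming over breakpoints, exhaustive in the segment
    boundaries.
    """
    seg = (prefix[:, None, :] - prefix[:, :, None]).min(axis=0)  # (n+1, n+1), j -> i
    n1 = seg.shape[0]
    seg[np.tril_indices(n1, k=-1)] = np.inf  # segments must advance (j <= i)
    best = np.empty(max_segments)
    f = seg[0, :].copy()  # one segment covering [0, i)
    best[0] = f[-1]
    for s in range(1, max_segments):
        f = (f[:, None] + seg).min(axis=0)
        best[s] = f[-1]
    return best


def classify_vs_reference(
    seq: str,
    refs: list[str],
    tm: TransitionModel | None = None,
    improvement: int = 3,
    dist_threshold: float = 0.15,
) -> ReferenceLabel:
    """Label a sequence Good / Bimera / Trimera / Quadramera / Unclassified.

    The best single-reference match is compared with the best 1-, 2- and
    3-breakpoint spliced reconstructions; each extra breakpoint must improve
    the match by at least ``improvement`` nucleotides to promote the label.
    Whatever the promotion chain says, the final label requires the error-
    corrected distance of the winning reconstruction to be below
    ``dist_threshold``, else the sequence is Unclassified.
    """
    if not refs:
        raise ValueError("need at least one reference")
    if tm is None:
        tm = TransitionModel.default()
    diffs, costs = _ref_profiles(seq, refs, tm)
    best_d = _multi_breakpoint_best(diffs, 4)  # 0..3 breakpoints
    best_c = _multi_breakpoint_best(costs, 4)
    level = 0
    while level < 3 and best_d[level + 1] <= best_d[level] - improvement:
        level += 1
    e = float(best_c[level]) / len(seq)
    chain = [int(best_d[k] - best_d[k + 1]) for k in range(3)]
    labels = [
        ChimeraClass.GOOD,
        ChimeraClass.BIMERA,
        ChimeraClass.TRIMERA,
        ChimeraClass.QUADRAMERA,
    ]
    label = labels[level] if e < dist_threshold else ChimeraClass.UNCLASSIFIED
    return ReferenceLabel(label=label, best_distance=e, improvement_chain=chain)


# ---------------------------------------------------------------------------
# OTU construction


@dataclass
class OTUPartition:
    cutoff: float  # percent sequence difference
    clusters: list[set[str]]
    linkage: str


def percent_difference_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise percent differences from exact global alignment.

    Unit scoring (match 0 / mismatch 1 / gap 1); percent difference =
    (mismatches + gap columns) / alignment columns x 100.  This is separate
    from the PCR error-model alignment used for denoising distances.
    """
    n = len(seqs)
    sub = unit_cost_matrix()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align(seqs[i], seqs[j], sub=sub, gap=1.0, homopolymer_aware=False)
            out[i, j] = out[j, i] = 100.0 * aln.cost / aln.n_columns
    return out


def cluster_otus(
    seqs: list[tuple[str, str]],
    linkage: str = "complete",
    cutoffs: list[float] | None = None,
) -> list[OTUPartition]:
    """Hierarchical OTUs at each percent-difference cutoff.

    ``seqs`` is (id, sequence) pairs; default cutoffs run 0..5% at 0.1%
    increments.  ``linkage`` is ``complete`` or ``average``.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if linkage not in ("complete", "average"):
        raise ValueError("linkage must be 'complete' or 'average'")
    if cutoffs is None:
        cutoffs = [round(0.1 * k, 1) for k in range(0, 51)]
    ids = [s[0] for s in seqs]
    if len(seqs) == 1:
        return [OTUPartition(c, [{ids[0]}], linkage) for c in cutoffs]
    dm = percent_difference_matrix([s[1] for s in seqs])
    tree = _linkage(squareform(dm, checks=False), method=linkage)
    out = []
    for c in cutoffs:
        labels = fcluster(tree, t=c, criterion="distance")
        clusters: dict[int, set[str]] = {}
        for name, lab in zip(ids, labels):
            clusters.setdefault(lab, set()).add(name)
        out.append(OTUPartition(cutoff=c, clusters=list(clusters.values()), linkage=linkage))
    return out


def otu_accuracy(
    denoised: list[tuple[str, str]],
    refs: list[tuple[str, str]],
    cutoff: float,
    linkage: str = "complete",
) -> tuple[int, int, int]:
    """Joint-cluster denoised output with references; count OTU fates.

    Returns (good, missed, noise): OTUs containing both reference and
    denoised sequences, reference-only OTUs (diversity missed), and
    denoised-only OTUs (residual noise).
    """
    if not denoised or not refs:
        raise ValueError("both sequence sets must be non-empty")
    ref_ids = {f"ref::{name}" for name, _ in refs}
    joint = [(f"ref::{name}", seq) for name, seq in refs]
    joint += [(f"dn::{name}", seq) for name, seq in denoised]
    part = cluster_otus(joint, linkage=linkage, cutoffs=[cutoff])[0]
    good = missed = noise = 0
    for cluster in part.clusters:
        has_ref = any(m in ref_ids for m in cluster)
        has_dn = any(m not in ref_ids for m in cluster)
        if has_ref and has_dn:
            good += 1
        elif has_ref:
            missed += 1
        else:
            noise += 1
    return good, missed, noise
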