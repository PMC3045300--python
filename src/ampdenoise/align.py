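"""Global pairwise alignment with homopolymer-aware gap costs.

One Needleman-Wunsch core serves three consumers: the PCR-error sequence
distance (substitution costs are -log transition probabilities; a gap that
extends or contracts a homopolymer is cheap because it is the signature of
residual pyrosequencing noise), the chimera parent search, and the unit-cost
alignment used for OTU percent differences.

The gap rule: a gap column costs ``hgap`` when the inserted/deleted base
equals either base flanking the gap point in the *other* (ungapped) sequence,
else ``gap``.  Traceback ties resolve diagonal > up (delete) > left (insert),
so alignments are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["Alignment", "encode", "align", "unit_cost_matrix", "prefix_costs"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from None


def unit_cost_matrix() -> np.ndarray:
    """Match 0 / mismatch 1 — the scoring behind OTU percent differences."""
    return (1.0 - np.eye(4)).astype(np.float64)


@njit(cache=True)
def _gap_cost(base, other, pos, gap, hgap, use_hp):
    if use_hp:
        if pos >= 1 and other[pos - 1] == base:
            return hgap
        if pos < other.shape[0] and other[pos] == base:
            return hgap
    return gap


@njit(cache=True)
def _nw_fill(a, b, sub, gap, hgap, use_hp):
    n = a.shape[0]
    m = b.shape[0]
    D = np.empty((n + 1, m + 1), dtype=np.float64)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up/delete, 2 left/insert
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 0] = D[i - 1, 0] + _gap_cost(a[i - 1], b, 0, gap, hgap, use_hp)
        P[i, 0] = 1
    for j in range(1, m + 1):
        D[0, j] = D[0, j - 1] + _gap_cost(b[j - 1], a, 0, gap, hgap, use_hp)
        P[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = D[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            ptr = 0
            up = D[i - 1, j] + _gap_cost(a[i - 1], b, j, gap, hgap, use_hp)
            if up < best:
                best = up
                ptr = 1
            left = D[i, j - 1] + _gap_cost(b[j - 1], a, i, gap, hgap, use_hp)
            if left < best:
                best = left
                ptr = 2
            D[i, j] = best
            P[i, j] = ptr
    return D, P


def prefix_costs(
    a: str,
    b: str,
    sub: np.ndarray,
    gap: float,
    hgap: float | None = None,
    homopolymer_aware: bool = True,
) -> np.ndarray:
    """Optimal cost of aligning each prefix ``a[:i]`` against *any* prefix of b.

    Row minima of the Needleman-Wunsch cost matrix: entry ``i`` is the best
    global alignment cost of ``a[:i]`` to ``b[:j]`` over all ``j`` — no charge
    for the unused remainder of ``b``.  Running this on the reversed
    sequences gives suffix costs; together they score spliced (chimeric)
    reconstructions exactly, each side independently optimally aligned.
    """
    if hgap is None:
        hgap = gap
    ca, cb = encode(a), encode(b)
    use_hp = homopolymer_aware and hgap != gap
    D, _ = _nw_fill(ca, cb, np.asarray(sub, dtype=np.float64), float(gap), float(hgap), use_hp)
    return D.min(axis=1)


@dataclass
class Alignment:
    """A global alignment as paired gapped strings plus per-column costs."""

    a_aligned: str
    b_aligned: str
    cost: float
    column_costs: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.a_aligned)

    def differences(self) -> int:
        """Mismatch plus gap columns — the 'nucleotide differences' count."""
        return sum(1 for x, y in zip(self.a_aligned, self.b_aligned) if x != y)

    def columns(self):
        return list(zip(self.a_aligned, self.b_aligned))


def align(
    a: str,
    b: str,
    sub: np.ndarray,
    gap: float,
    hgap: float | None = None,
    homopolymer_aware: bool = True,
) -> Alignment:
    """Minimum-cost global alignment of ``a`` against ``b``.

    ``sub`` is a 4x4 cost matrix in A/C/G/T order.  With
    ``homopolymer_aware=False`` (or ``hgap == gap``) this is plain
    Needleman-Wunsch with linear gap cost.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if hgap is None:
        hgap = gap
    ca, cb = encode(a), encode(b)
    use_hp = homopolymer_aware and hgap != gap
    D, P = _nw_fill(ca, cb, np.asarray(sub, dtype=np.float64), float(gap), float(hgap), use_hp)
    i, j = len(ca), len(cb)
    cols_a: list[str] = []
    cols_b: list[str] = []
    costs: list[float] = []
    while i > 0 or j > 0:
        ptr = P[i, j]
        if i > 0 and j > 0 and ptr == 0:
            cols_a.append(_BASES[ca[i - 1]])
            cols_b.append(_BASES[cb[j - 1]])
            costs.append(float(sub[ca[i - 1], cb[j - 1]]))
            i -= 1
            j -= 1
        elif i > 0 and (ptr == 1 or j == 0):
            cols_a.append(_BASES[ca[i - 1]])
            cols_b.append("-")
            costs.append(float(_gap_cost(ca[i - 1], cb, j, gap, hgap, use_hp)))
            i -= 1
        else:
            cols_a.append("-")
            cols_b.append(_BASES[cb[j - 1]])
            costs.append(float(_gap_cost(cb[j - 1], ca, i, gap, hgap, use_hp)))
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    costs.reverse()
    return Alignment(
        a_aligned="".join(cols_a),
        b_aligned="".join(cols_b),
        cost=float(D[len(ca), len(cb)]),
        column_costs=np.array(costs),
    )
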