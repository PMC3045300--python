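"""Stage one: EM mixture clustering of flowgrams to remove pyrosequencing noise.

Flowgrams are clustered around candidate true sequences using the flow-level
distance d' (mean per-flow -log P(f|n)); candidates are restricted to the
perfect flowgrams obtained by rounding the observed flowgrams, so every
denoised sequence was actually observed and reads remain traceable.  No
flowgram alignment is performed: indel-like events from pyrosequencing itself
are removed upstream by the filter's frame truncation, so this stage sees
pure intensity noise.

The kernel scale ``sigma_p = 1/60`` and the complete-linkage initialisation
cut-off ``cut_p = 0.01`` are the stage's two parameters.  Because d' carries
each read's per-flow entropy as an additive constant that cancels in the
responsibilities, the initialisation distance between two reads is centred on
each read's distance to its own rounded flowgram before symmetrising — the
result is ~0 for reads that round identically and of order
``|d(f|n) - d(f|n')| / M`` otherwise, the scale on which ``cut_p`` operates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em import MixtureState, init_complete_linkage, run_em
from .flowgrams import Flowgram, PerfectFlowgram, flows_to_sequence
from .intensity import IntensityModel, distance_matrix

__all__ = ["DenoisedComponent", "PyronoiseResult", "run_pyronoise"]

DEFAULT_SIGMA_P = 1.0 / 60.0
DEFAULT_CUT_P = 0.01


@dataclass
class DenoisedComponent:
    sequence: str
    runs: np.ndarray  # perfect-flowgram runs of the component centre
    abundance: float  # mapped read count


@dataclass
class PyronoiseResult:
    components: list[DenoisedComponent]
    mapping: dict[str, int]  # read_id -> index into components
    state: MixtureState

    @property
    def total_reads(self) -> int:
        return len(self.mapping)


def _unique_candidates(rounded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique rounded flowgrams ordered (abundance desc, sequence lex asc).

    Returns the P x M candidate run matrix and, per read, the index of its own
    rounding.  The ordering fixes all argmin/argmax tie-breaks.
    """
    uniq, inverse, counts = np.unique(rounded, axis=0, return_inverse=True, return_counts=True)
    seqs = [flows_to_sequence(PerfectFlowgram(runs=u)) for u in uniq]
    order = sorted(range(len(uniq)), key=lambda k: (-counts[k], seqs[k]))
    rank = np.empty(len(uniq), dtype=np.int64)
    rank[order] = np.arange(len(uniq))
    return uniq[order], rank[inverse]


def initialization_distances(C: np.ndarray, cand_of_read: np.ndarray) -> np.ndarray:
    """Symmetric, self-centred flowgram distances for the initial clustering.

    ``d_init(a, b) = 0.5 * [(d'(a, U_b) - d'(a, U_a)) + (d'(b, U_a) - d'(b, U_b))]``
    clipped at zero; the self terms remove the entropy baseline that is
    constant per read and irrelevant to the mixture (it cancels in the E-step
    row normalisation).
    """
    centred = C - C[np.arange(C.shape[0]), cand_of_read][:, None]
    m = centred[:, cand_of_read]  # m[a, b] = centred d'(f_a, U_b)
    d = 0.5 * (m + m.T)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def run_pyronoise(
    flowgrams: list[Flowgram],
    model: IntensityModel,
    sigma_p: float = DEFAULT_SIGMA_P,
    cut_p: float = DEFAULT_CUT_P,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> PyronoiseResult:
    """Denoise filtered flowgrams; returns components with read-count abundances
    and a read -> component mapping.

    All flowgrams must share one truncated flow count.  Each read maps to its
    argmax-responsibility component; components to which no read maps are
    dropped from the output, and components converging on the same candidate
    sequence are merged.
    """
    if not flowgrams:
        raise ValueError("need at least one filtered flowgram")
    lengths = {len(fg) for fg in flowgrams}
    if len(lengths) > 1:
        raise ValueError(f"flowgrams must share one flow count, got {sorted(lengths)}")

    rounded = np.stack([fg.rounded_runs() for fg in flowgrams])
    candidates, cand_of_read = _unique_candidates(rounded)
    C = distance_matrix(flowgrams, candidates, model)

    labels = init_complete_linkage(initialization_distances(C, cand_of_read), cut_p)
    state = run_em(C, labels, sigma=sigma_p, max_iter=max_iter, tol=tol)

    assign = state.hard_assignments()
    centre = state.candidate_idx  # per component, candidate index

    # collapse components that settled on the same candidate; drop unmapped ones
    read_cand = centre[assign]  # per read, winning candidate
    used, counts = np.unique(read_cand, return_counts=True)
    order = sorted(range(len(used)), key=lambda k: (-counts[k], int(used[k])))
    components = []
    cand_to_out: dict[int, int] = {}
    for out_idx, k in enumerate(order):
        cand = int(used[k])
        runs = candidates[cand]
        components.append(
            DenoisedComponent(
                sequence=flows_to_sequence(PerfectFlowgram(runs=runs)),
                runs=runs,
                abundance=float(counts[k]),
            )
        )
        cand_to_out[cand] = out_idx
    mapping = {
        fg.read_id: cand_to_out[int(read_cand[i])] for i, fg in enumerate(flowgrams)
    }
    return PyronoiseResult(components=components, mapping=mapping, state=state)
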