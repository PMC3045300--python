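"""Synthetic mock communities: PCR-mutated reads, chimeras, and flowgrams.

The generator emulates the structure of amplicon control experiments — known
templates mixed at known concentrations, amplified and pyrosequenced — with
ground truth attached to every read, so each pipeline stage is testable
without any sequencing data.  Three noise layers are modelled:

* PCR point substitutions: a molecule drawn after ``c`` ideal-doubling cycles
  was newly synthesised in Binomial(c, 1/2) of them; each synthesis event
  substitutes each base with the per-cycle transition rates, giving an
  accumulated per-base error frequency of about ``p * c / 2``.
* PCR chimeras: incomplete extension splices two extant molecules at a
  breakpoint; because the splice happens in a cycle before the last, every
  chimera's parents end up at least as abundant as the chimera itself, the
  ordering the chimera classifier exploits.
* Flow intensity noise: each flow's signal is drawn from P(f|n) for the true
  run length, by default the package's parametric description of 454-like
  intensity distributions.

Molecules are tracked by counts, not individual lineages; replication is
ideal doubling.  This keeps the two properties the algorithms rely on —
errors are rare and parent abundance dominates — while ignoring primer bias
and CAFIE/phasing effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flowgrams import DEFAULT_FLOW_ORDER, Flowgram, Platform, sequence_to_flows
from .intensity import IntensityModel, default_intensity_model
from .seqnoise import TransitionModel, PCR_CYCLES

__all__ = [
    "MockCommunity",
    "AmpliconRead",
    "default_per_cycle_rates",
    "random_references",
    "simulate_amplicon_pool",
    "simulate_flowgrams",
]

_BASES = "ACGT"


def default_per_cycle_rates(tm: TransitionModel | None = None) -> np.ndarray:
    """4x4 per-synthesis-event substitution probabilities.

    The measured whole-run transition frequencies are scaled row-wise so each
    template base's total off-diagonal rate equals its measured per-cycle
    rate; the diagonal absorbs the remainder.
    """
    if tm is None:
        tm = TransitionModel.default()
    probs = tm.probs()
    out = np.zeros((4, 4))
    for i, base in enumerate(_BASES):
        off = probs[i].copy()
        off[i] = 0.0
        out[i] = off * (tm.per_cycle[base] / off.sum())
        out[i, i] = 1.0 - out[i].sum()
    return out


@dataclass
class MockCommunity:
    """Study design for one synthetic data set.

    ``abundances`` must sum to 1 (even or log-spread mixtures); chimeras take
    ``chimera_rate`` of the reads, spliced at breakpoints uniform over
    ``breakpoint_window`` (kept inside the analysed read prefix so the splice
    is observable after truncation).
    """

    references: list[str]
    abundances: np.ndarray
    seed: int = 0
    n_reads: int = 2000
    cycles: int = PCR_CYCLES
    per_cycle_rates: np.ndarray = field(default_factory=default_per_cycle_rates)
    chimera_rate: float = 0.0
    breakpoint_window: tuple[int, int] = (30, 190)
    max_chimera_count: int = 12

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.abundances) != len(self.references):
            raise ValueError("one abundance per reference")
        if np.any(self.abundances <= 0) or abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must be positive and sum to 1")
        if not 0.0 <= self.chimera_rate < 1.0:
            raise ValueError("chimera_rate must be in [0, 1)")


@dataclass
class AmpliconRead:
    read_id: str
    seq: str
    origin: str  # reference or chimera-species label
    is_chimera: bool
    parents: tuple[str, str] | None
    breakpoint: int | None
    n_subs: int


def random_references(
    n: int,
    length: int = 300,
    seed: int = 0,
    max_homopolymer: int = 6,
    min_bases_in: tuple[int, int] | None = (360, 230),
) -> list[str]:
    """Random templates suitable for flow simulation.

    Rejection-samples sequences whose homopolymers stay callable
    (<= ``max_homopolymer``) and, if ``min_bases_in = (F, B)`` is given, whose
    first F flows cover at least B bases — so a truncated flowgram still spans
    the sequence prefix the later stages analyse.
    """
    rng = np.random.default_rng(seed)
    refs: list[str] = []
    while len(refs) < n:
        seq = "".join(rng.choice(list(_BASES), size=length))
        runs = sequence_to_flows(seq).runs
        if runs.max() > max_homopolymer:
            continue
        if min_bases_in is not None:
            flows, bases = min_bases_in
            if runs[:flows].sum() < bases:
                continue
        if seq in refs:
            continue
        refs.append(seq)
    return refs


def _mutate(seq: str, generations: int, rates: np.ndarray, rng: np.random.Generator):
    codes = np.array([_BASES.index(c) for c in seq])
    p_tot = 1.0 - np.diag(rates)
    p_sub = 1.0 - (1.0 - p_tot[codes]) ** generations
    hits = np.nonzero(rng.random(len(codes)) < p_sub)[0]
    for i in hits:
        row = rates[codes[i]].copy()
        row[codes[i]] = 0.0
        codes[i] = rng.choice(4, p=row / row.sum())
    if hits.size == 0:
        return seq, 0
    return "".join(_BASES[c] for c in codes), int(hits.size)


def simulate_amplicon_pool(mc: MockCommunity) -> list[AmpliconRead]:
    """Draw a pool of amplicon sequences with ground truth.

    Reproducible from ``mc.seed``.  Chimeric reads are grouped into species
    (distinct spliced sequences); each species' read count is kept at or below
    both parents' counts, else the abundance ordering the classifier relies on
    would be violated (an over-high ``chimera_rate`` raises an error).
    """
    rng = np.random.default_rng(mc.seed)
    n_chim = int(round(mc.chimera_rate * mc.n_reads))
    counts = rng.multinomial(mc.n_reads - n_chim, mc.abundances)

    ref_ids = [f"ref{str(i).zfill(2)}" for i in range(len(mc.references))]
    species: list[tuple[str, str, tuple[str, str], int, int]] = []
    remaining = n_chim
    lo, hi = mc.breakpoint_window
    while remaining > 0:
        size = int(min(remaining, rng.integers(1, mc.max_chimera_count + 1)))
        placed = False
        for _ in range(100):
            pa, pb = rng.choice(len(mc.references), size=2, replace=False, p=mc.abundances)
            if counts[pa] < size or counts[pb] < size:
                continue
            bp = int(rng.integers(lo, hi))
            seq = mc.references[pa][:bp] + mc.references[pb][bp:]
            if seq in mc.references or any(s[1] == seq for s in species):
                continue
            label = f"chim{str(len(species)).zfill(2)}"
            species.append((label, seq, (ref_ids[pa], ref_ids[pb]), bp, size))
            placed = True
            break
        if not placed:
            raise ValueError("chimera_rate too high to satisfy the parent-abundance constraint")
        remaining -= size

    reads: list[AmpliconRead] = []
    templates: list[tuple[str, str, bool, tuple[str, str] | None, int | None, int]] = []
    for i, ref in enumerate(mc.references):
        templates.append((ref_ids[i], ref, False, None, None, int(counts[i])))
    for label, seq, parents, bp, size in species:
        templates.append((label, seq, True, parents, bp, size))

    idx = 0
    for origin, seq, is_chim, parents, bp, size in templates:
        for _ in range(size):
            g = int(rng.binomial(mc.cycles, 0.5))
            mutated, n_subs = _mutate(seq, g, mc.per_cycle_rates, rng)
            reads.append(
                AmpliconRead(
                    read_id=f"read{str(idx).zfill(5)}",
                    seq=mutated,
                    origin=origin,
                    is_chimera=is_chim,
                    parents=parents,
                    breakpoint=bp,
                    n_subs=n_subs,
                )
            )
            idx += 1
    return reads


def simulate_flowgrams(
    seqs: list[tuple[str, str]],
    model: IntensityModel | None = None,
    seed: int = 0,
    platform: Platform = Platform.FLX,
    flow_order: str = DEFAULT_FLOW_ORDER,
) -> list[Flowgram]:
    """Draw one flowgram per (read_id, sequence) from P(f|n).

    The true runs come from the perfect flowgram of each sequence, padded
    with zero runs (pure background signal) past the template end and cut at
    the platform's raw flow count; each flow's intensity is then an
    independent draw from the model's column for its run length.
    """
    if model is None:
        model = default_intensity_model()
    rng = np.random.default_rng(seed)
    probs = model.probabilities()
    probs = probs / probs.sum(axis=0, keepdims=True)
    n_flows = platform.raw_flows

    runs = np.zeros((len(seqs), n_flows), dtype=np.int64)
    for r, (_, seq) in enumerate(seqs):
        pf = sequence_to_flows(seq, flow_order).runs
        m = min(len(pf), n_flows)
        runs[r, :m] = pf[:m]
    clipped = np.clip(runs, 0, model.max_run)

    bins = np.zeros_like(runs)
    for n in range(model.max_run + 1):
        mask = clipped == n
        k = int(mask.sum())
        if k:
            bins[mask] = rng.choice(model.n_bins, size=k, p=probs[:, n])
    values = np.round(bins * model.bin_width, 2)
    return [
        Flowgram(read_id=name, values=values[r], flow_order=flow_order, platform=platform)
        for r, (name, _) in enumerate(seqs)
    ]
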