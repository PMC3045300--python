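"""Flowgram containers, interchange formats, and read quality filtering.

A 454 pyrosequencing read is a *flowgram*: one real-valued light intensity per
nucleotide flow, the flows cycling through a fixed order (``TACG`` by default).
A noise-free sequence maps to a *perfect flowgram* whose entries are the
integer homopolymer lengths met by each flow.  This module holds the data
types, the greedy sequence <-> flow conversions, readers/writers for SFF and a
plain TSV flow table, and the strict pre-clustering filter (noisy-signal
truncation and end trimming).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "Platform",
    "Flowgram",
    "PerfectFlowgram",
    "FilterPolicy",
    "FilterRejection",
    "read_flowgrams",
    "write_flowtable",
    "sequence_to_flows",
    "flows_to_sequence",
    "filter_and_truncate",
    "read_weighted_fasta",
    "write_weighted_fasta",
]

DEFAULT_FLOW_ORDER = "TACG"


class Platform(str, Enum):
    FLX = "FLX"
    TITANIUM = "TITANIUM"

    @property
    def raw_flows(self) -> int:
        return 400 if self is Platform.FLX else 800

    @property
    def end_truncation_flow(self) -> int:
        # drop the last 10% of flows, where noise increases
        return 360 if self is Platform.FLX else 720


@dataclass
class Flowgram:
    """One read's ordered flow intensities (hundredths precision)."""

    read_id: str
    values: np.ndarray
    flow_order: str = DEFAULT_FLOW_ORDER
    platform: Platform = Platform.FLX

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("flow values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError(f"negative flow intensity in read {self.read_id!r}")

    def __len__(self) -> int:
        return len(self.values)

    def rounded_runs(self) -> np.ndarray:
        """Standard base-calling: round each intensity to an integer run length.

        Uses round-half-up so an ambiguous 1.50 calls as 2 (numpy's default
        would round half to even).
        """
        return np.floor(self.values + 0.5).astype(np.int64)

    def to_perfect(self) -> "PerfectFlowgram":
        return PerfectFlowgram(runs=self.rounded_runs(), flow_order=self.flow_order)


@dataclass
class PerfectFlowgram:
    """Integer flowgram a sequence would produce with zero noise."""

    runs: np.ndarray
    flow_order: str = DEFAULT_FLOW_ORDER

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=np.int64)
        if np.any(self.runs < 0):
            raise ValueError("run lengths must be non-negative")

    def __len__(self) -> int:
        return len(self.runs)

    def sequence(self) -> str:
        return flows_to_sequence(self)


def sequence_to_flows(seq: str, flow_order: str = DEFAULT_FLOW_ORDER) -> PerfectFlowgram:
    """Greedy left-to-right encoding of a sequence into perfect flow runs.

    Each flow reads off the length of the homopolymer of its nucleotide at the
    current position (0 if the next base differs).  Output is zero-padded to a
    whole frame of ``len(flow_order)`` flows.
    """
    seq = seq.upper()
    if re.search(r"[^ACGT]", seq):
        raise ValueError("sequence must contain only A/C/G/T (no ambiguity codes)")
    frame = len(flow_order)
    runs: list[int] = []
    pos = 0
    n = len(seq)
    flow = 0
    while pos < n:
        base = flow_order[flow % frame]
        run = 0
        while pos < n and seq[pos] == base:
            run += 1
            pos += 1
        runs.append(run)
        flow += 1
    while len(runs) % frame != 0:
        runs.append(0)
    return PerfectFlowgram(runs=np.array(runs, dtype=np.int64), flow_order=flow_order)


def flows_to_sequence(pf: PerfectFlowgram) -> str:
    """Inverse of :func:`sequence_to_flows` up to trailing zero flows."""
    frame = len(pf.flow_order)
    out: list[str] = []
    for i, run in enumerate(pf.runs):
        if run > 0:
            out.append(pf.flow_order[i % frame] * int(run))
    return "".join(out)


# ---------------------------------------------------------------------------
# interchange formats


def read_flowgrams(
    path: str | Path,
    format: str = "FLOWTABLE",
    flow_order: str = DEFAULT_FLOW_ORDER,
    platform: Platform = Platform.FLX,
) -> list[Flowgram]:
    """Read flowgrams from an SFF file or a FLOWTABLE TSV.

    FLOWTABLE is the dependency-free interchange format: one row per read,
    tab-separated, ``read_id`` followed by the flow values.
    """
    fmt = format.upper()
    path = Path(path)
    if fmt == "FLOWTABLE":
        out: list[Flowgram] = []
        with open(path) as fh:
            for idx, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed flow-table record {idx}: need id and values")
                try:
                    values = np.array([float(v) for v in parts[1:]], dtype=float)
                except ValueError as exc:
                    raise ValueError(f"malformed flow-table record {idx}: {exc}") from None
                if np.any(values < 0):
                    raise ValueError(f"malformed flow-table record {idx}: negative intensity")
                out.append(
                    Flowgram(read_id=parts[0], values=values, flow_order=flow_order, platform=platform)
                )
        return out
    if fmt == "SFF":
        out = []
        for idx, rec in enumerate(SeqIO.parse(str(path), "sff")):
            try:
                values = np.array(rec.annotations["flow_values"], dtype=float) / 100.0
                order = str(rec.annotations.get("flow_chars", flow_order))
            except KeyError as exc:
                raise ValueError(f"malformed SFF record {idx}: missing {exc}") from None
            if np.any(values < 0):
                raise ValueError(f"malformed SFF record {idx}: negative intensity")
            out.append(Flowgram(read_id=rec.id, values=values, flow_order=order, platform=platform))
        return out
    raise ValueError(f"unknown flowgram format: {format!r} (expected SFF or FLOWTABLE)")


def write_flowtable(flowgrams: Iterable[Flowgram], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fg in flowgrams:
            vals = "\t".join(f"{v:.2f}" for v in fg.values)
            fh.write(f"{fg.read_id}\t{vals}\n")


_COUNT_RE = re.compile(r"_(\d+)$")


def read_weighted_fasta(path: str | Path) -> list[tuple[str, str, float]]:
    """Read FASTA with ``>id_count`` abundance suffixes; count defaults to 1."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_RE.search(rec.id)
        weight = float(m.group(1)) if m else 1.0
        name = rec.id[: m.start()] if m else rec.id
        out.append((name, str(rec.seq).upper(), weight))
    return out


def write_weighted_fasta(records: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, weight in records:
            w = int(round(weight))
            fh.write(f">{name}_{w}\n{seq}\n")


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterPolicy:
    """Strict pre-clustering read filter.

    Signal intensities in ``noise_window`` mark noisy reads; a frame of four
    flows all below ``min_signal`` marks the template end.  Reads whose first
    such event falls before ``min_clean_flow`` are rejected; survivors are
    truncated at ``end_truncation_flow`` to drop the noisy read tails.
    """

    noise_window: tuple[float, float] = (0.5, 0.7)  # half-open [low, high)
    min_signal: float = 0.5
    min_clean_flow: int = 360
    end_truncation_flow: int = 360
    primer: str = ""
    tag: str = ""

    def __post_init__(self) -> None:
        if self.min_clean_flow > self.end_truncation_flow:
            raise ValueError("min_clean_flow must be <= end_truncation_flow")

    @classmethod
    def for_platform(cls, platform: Platform, primer: str = "", tag: str = "") -> "FilterPolicy":
        return cls(
            end_truncation_flow=platform.end_truncation_flow,
            primer=primer,
            tag=tag,
        )


@dataclass
class FilterRejection:
    read_id: str
    reason: str


def _iupac_regex(primer: str) -> re.Pattern:
    parts = []
    for ch in primer.upper():
        bases = ambiguous_dna_values.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC code in primer: {ch!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def filter_and_truncate(
    fg: Flowgram, policy: FilterPolicy, seq: str | None = None
) -> Flowgram | FilterRejection:
    """Apply the strict read filter; return a truncated flowgram or a rejection.

    Order of checks: exact (IUPAC-aware) tag+primer match at the start of the
    called sequence; clean length = the earlier of the first flow with a value
    in the noise window and the first frame of four flows with no signal >=
    ``min_signal``; reject if clean length < ``min_clean_flow``; else truncate
    to ``min(clean length rounded down to a whole frame, end_truncation_flow)``.
    """
    values = fg.values
    frame = len(fg.flow_order)

    if policy.tag or policy.primer:
        called = seq if seq is not None else flows_to_sequence(fg.to_perfect())
        prefix = (policy.tag or "").upper() + (policy.primer or "")
        if not _iupac_regex(prefix).match(called.upper()):
            return FilterRejection(fg.read_id, "primer/tag mismatch")

    lo, hi = policy.noise_window
    noisy = np.nonzero((values >= lo) & (values < hi))[0]
    first_noisy = int(noisy[0]) if noisy.size else len(values)

    n_frames = len(values) // frame
    framed = values[: n_frames * frame].reshape(n_frames, frame)
    weak = np.nonzero(~(framed >= policy.min_signal).any(axis=1))[0]
    first_weak_flow = int(weak[0]) * frame if weak.size else len(values)

    clean = min(first_noisy, first_weak_flow)
    if clean < policy.min_clean_flow:
        if len(values) < policy.min_clean_flow:
            return FilterRejection(fg.read_id, "too short")
        return FilterRejection(fg.read_id, f"noisy before {policy.min_clean_flow}")

    keep = min((clean // frame) * frame, policy.end_truncation_flow)
    return replace(fg, values=values[:keep].copy())


def write_rejection_log(rejections: Sequence[FilterRejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rejections:
            fh.write(f"{r.read_id}\t{r.reason}\n")
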