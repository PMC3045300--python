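"""Empirical flow-intensity distributions P(f|n) and the flowgram distance d'.

Pyrosequencing miscalls arise because the light intensity ``f`` emitted by a
homopolymer of length ``n`` is spread around ``n`` with a variance that grows
with ``n``.  The model here is a binned lookup of ``d(f|n) = -log P(f|n)``
calibrated from reads of known origin; the distance between an observed
flowgram and a hypothesised perfect flowgram is the mean per-flow ``d`` over
the common length:

    d'(f, U) = sum_i -log P(f_i | u_i) / M

Unobserved (f, n) cells take a large finite cap so arithmetic stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .flowgrams import Flowgram, PerfectFlowgram

__all__ = [
    "IntensityModel",
    "calibrate_intensity_model",
    "flowgram_distance",
    "distance_matrix",
    "parametric_flow_probs",
    "default_intensity_model",
]

DEFAULT_BIN_WIDTH = 0.01
DEFAULT_MAX_RUN = 9
DEFAULT_CAP = 100.0


@dataclass
class IntensityModel:
    """Lookup of per-signal distances d(f|n) = -log P(f|n).

    ``neg_log_prob`` is indexed ``[bin, run]`` with ``n_bins x (max_run+1)``
    entries; intensities are clamped to ``[0, (n_bins-1)*bin_width]`` and runs
    above ``max_run`` use the ``max_run`` row (an approximation for the very
    long homopolymers the model was never calibrated on).
    """

    neg_log_prob: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    max_run: int = DEFAULT_MAX_RUN
    distance_cap: float = DEFAULT_CAP

    def __post_init__(self) -> None:
        self.neg_log_prob = np.asarray(self.neg_log_prob, dtype=float)
        if self.neg_log_prob.ndim != 2 or self.neg_log_prob.shape[1] != self.max_run + 1:
            raise ValueError("neg_log_prob must be (n_bins, max_run+1)")
        if np.any(self.neg_log_prob < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.neg_log_prob.shape[0]

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        # the epsilon keeps two-decimal values on their bin edge (0.93/0.01
        # is 92.999... in floating point)
        b = np.floor(np.asarray(values, dtype=float) / self.bin_width + 1e-9).astype(np.int64)
        return np.clip(b, 0, self.n_bins - 1)

    def run_index(self, runs: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(runs, dtype=np.int64), 0, self.max_run)

    def probabilities(self) -> np.ndarray:
        """exp(-d) per cell; each column sums to <= 1 (+ rounding)."""
        return np.exp(-self.neg_log_prob)

    # -- plain-text serialization (the pipeline's one calibration artifact) --

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# bin_width\t{self.bin_width}\n")
            fh.write(f"# max_run\t{self.max_run}\n")
            fh.write(f"# distance_cap\t{self.distance_cap}\n")
            for row in self.neg_log_prob:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "IntensityModel":
        header: dict[str, float] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, val = line[1:].split("\t")
                    header[key.strip()] = float(val)
                else:
                    rows.append([float(v) for v in line.split("\t")])
        return cls(
            neg_log_prob=np.array(rows),
            bin_width=header["bin_width"],
            max_run=int(header["max_run"]),
            distance_cap=header["distance_cap"],
        )


def calibrate_intensity_model(
    flowgrams: list[Flowgram],
    truth: list[PerfectFlowgram],
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_run: int = DEFAULT_MAX_RUN,
    distance_cap: float = DEFAULT_CAP,
) -> IntensityModel:
    """Estimate P(f|n) empirically from reads paired with their true runs.

    Every aligned flow position contributes one (binned f, n) observation; the
    per-``n`` frequencies are turned into distances with ``-log``; empty cells
    get ``distance_cap``, and an ``n`` with no observations at all gets a
    warning and a full cap row.
    """
    if len(flowgrams) != len(truth):
        raise ValueError("flowgrams and truth must pair one-to-one")
    n_bins = int(round((max_run + 1) / bin_width))
    counts = np.zeros((n_bins, max_run + 1), dtype=np.int64)
    for fg, pf in zip(flowgrams, truth):
        m = min(len(fg), len(pf))
        bins = np.clip(np.floor(fg.values[:m] / bin_width + 1e-9).astype(np.int64), 0, n_bins - 1)
        runs = np.clip(pf.runs[:m], 0, max_run)
        np.add.at(counts, (bins, runs), 1)
    totals = counts.sum(axis=0)
    neg_log = np.full((n_bins, max_run + 1), distance_cap)
    for n in range(max_run + 1):
        if totals[n] == 0:
            warnings.warn(f"no observations for run length {n}; row set to distance cap")
            continue
        observed = counts[:, n] > 0
        neg_log[observed, n] = np.minimum(
            -np.log(counts[observed, n] / totals[n]), distance_cap
        )
    return IntensityModel(neg_log, bin_width=bin_width, max_run=max_run, distance_cap=distance_cap)


def flowgram_distance(fg: Flowgram, pf: PerfectFlowgram, model: IntensityModel) -> float:
    """d'(f, U): mean per-flow -log P(f_i|u_i) over the common length.

    Asymmetric by construction: the first argument is the data, the second the
    hypothesis.
    """
    if len(fg) != len(pf):
        raise ValueError(f"flow count mismatch: {len(fg)} vs {len(pf)}")
    bins = model.bin_of(fg.values)
    runs = model.run_index(pf.runs)
    return float(model.neg_log_prob[bins, runs].mean())


def distance_matrix(
    flowgrams: list[Flowgram], candidates: np.ndarray, model: IntensityModel
) -> np.ndarray:
    """All d'(read i, candidate k) as an N x P matrix.

    ``candidates`` is a P x M integer array of perfect-flowgram runs.  The
    matrix is computed once per dataset; the EM only ever re-indexes it.
    """
    values = np.stack([fg.values for fg in flowgrams])
    bins = model.bin_of(values)  # N x M
    runs = model.run_index(candidates)  # P x M
    n, m = bins.shape
    out = np.empty((n, runs.shape[0]))
    for k in range(runs.shape[0]):
        out[:, k] = model.neg_log_prob[bins, runs[k][None, :]].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# parametric description of 454-like flow noise (shared with the simulator)


def parametric_flow_probs(
    max_run: int = DEFAULT_MAX_RUN,
    bin_width: float = DEFAULT_BIN_WIDTH,
    sd_base: float = 0.04,
    sd_slope: float = 0.03,
    zero_mean: float = 0.04,
    zero_sd: float = 0.03,
    outlier_weight: float = 1e-3,
) -> np.ndarray:
    """Binned P(f|n) columns mimicking observed 454 intensity distributions.

    Each run length ``n >= 1`` gets a discretised normal centred on ``n`` whose
    spread grows linearly with ``n`` (so miscall probability rises with
    homopolymer length), mixed with a small uniform outlier component on
    ``[n-1, n+1]`` that produces the occasional gross miscall; ``n = 0`` is a
    near-zero background signal truncated at 0.  Returns an
    ``n_bins x (max_run+1)`` column-stochastic matrix.
    """
    n_bins = int(round((max_run + 1) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    cols = np.zeros((n_bins, max_run + 1))
    for n in range(max_run + 1):
        if n == 0:
            mean, sd = zero_mean, zero_sd
        else:
            mean, sd = float(n), sd_base + sd_slope * n
        cdf = norm.cdf(edges, loc=mean, scale=sd)
        mass = np.diff(cdf)
        mass[0] += cdf[0]  # fold mass below 0 into the first bin
        mass[-1] += 1.0 - cdf[-1]
        lo, hi = max(0.0, n - 1.0), min(n + 1.0, edges[-1])
        uni = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)
        uni = uni / uni.sum()
        col = (1.0 - outlier_weight) * mass + outlier_weight * uni
        cols[:, n] = col / col.sum()
    return cols


def model_from_probs(
    probs: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    distance_cap: float = DEFAULT_CAP,
) -> IntensityModel:
    """Turn binned probability columns into an :class:`IntensityModel`."""
    floor = np.exp(-distance_cap)
    neg_log = np.where(probs > floor, -np.log(np.maximum(probs, floor)), distance_cap)
    return IntensityModel(
        neg_log_prob=neg_log,
        bin_width=bin_width,
        max_run=probs.shape[1] - 1,
        distance_cap=distance_cap,
    )


def default_intensity_model() -> IntensityModel:
    """The model implied by the package's parametric flow-noise description."""
    return model_from_probs(parametric_flow_probs())
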