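"""End-to-end orchestration: filter -> flowgram EM -> sequence EM -> chimera
removal, with full read provenance.

Every raw read is traceable to its fate: rejected by the filter (with
reason), denoised to a stage-one component, merged into a stage-two
sequence, and finally kept or removed as a chimera.  Given a seed and a
config the run is deterministic.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .chimera import ChimeraCandidate, LogisticModel, run_perseus
from .flowgrams import FilterPolicy, FilterRejection, Flowgram, Platform, filter_and_truncate
from .intensity import IntensityModel, default_intensity_model
from .pyronoise import PyronoiseResult, run_pyronoise
from .seqnoise import SeqnoiseResult, TransitionModel, WeightedSequence, run_seqnoise

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the published values."""

    platform: Platform = Platform.FLX
    sigma_p: float = 1.0 / 60.0
    cut_p: float = 0.01
    sigma_s: float = 0.033  # FLX default; 0.1 / 0.04 are the Titanium presets
    cut_s: float = 0.08
    gap: float = 15.0
    hgap: float = 4.0
    alpha: float = -7.5
    beta: float = 0.5
    dist_threshold: float = 0.15
    truncate_flows: int | None = None  # platform default (360 FLX / 720 Titanium)
    truncate_bases: int | None = None  # 220 FLX / 400 Titanium
    primer: str = ""
    tag: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.platform, str):
            self.platform = Platform(self.platform.upper())
        for name in ("sigma_p", "cut_p", "sigma_s", "cut_s", "gap", "hgap", "dist_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def flow_truncation(self) -> int:
        return self.truncate_flows or self.platform.end_truncation_flow

    @property
    def base_truncation(self) -> int:
        if self.truncate_bases:
            return self.truncate_bases
        return 220 if self.platform is Platform.FLX else 400

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key=value config text; explicit overrides win over the file."""
        values: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                values[key.strip()] = val.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name in values:
                raw = values[f.name]
                if f.name == "platform":
                    kwargs[f.name] = Platform(raw.upper())
                elif f.name in ("primer", "tag"):
                    kwargs[f.name] = raw
                elif f.name in ("truncate_flows", "truncate_bases", "seed"):
                    kwargs[f.name] = int(raw)
                else:
                    kwargs[f.name] = float(raw)
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


@dataclass
class PipelineResult:
    filtered: list[Flowgram]
    rejections: list[FilterRejection]
    stage1: PyronoiseResult
    stage2: SeqnoiseResult
    chimera_report: list[ChimeraCandidate]
    good_sequences: list[WeightedSequence]
    provenance: pd.DataFrame = field(repr=False)


def _log(verbose: bool, stage: str, t0: float, msg: str) -> None:
    if verbose:
        print(f"[{stage}] {time.perf_counter() - t0:.1f}s {msg}", file=sys.stderr)


def run_pipeline(
    flowgrams: list[Flowgram],
    config: PipelineConfig | None = None,
    model: IntensityModel | None = None,
    tm: TransitionModel | None = None,
    verbose: bool = False,
) -> PipelineResult:
    """Run the full denoising pipeline on raw flowgrams."""
    if config is None:
        config = PipelineConfig()
    if model is None:
        model = default_intensity_model()
    if tm is None:
        tm = TransitionModel.default()
    tm.gap_penalty = config.gap
    tm.homopolymer_gap_penalty = config.hgap
    t0 = time.perf_counter()

    policy = FilterPolicy(
        min_clean_flow=360,
        end_truncation_flow=config.flow_truncation,
        primer=config.primer,
        tag=config.tag,
    )
    filtered: list[Flowgram] = []
    rejections: list[FilterRejection] = []
    for fg in flowgrams:
        res = filter_and_truncate(fg, policy)
        (filtered if isinstance(res, Flowgram) else rejections).append(res)
    if len(filtered) + len(rejections) != len(flowgrams):
        raise RuntimeError("read conservation violated at the filter stage")
    _log(verbose, "filter", t0, f"{len(filtered)} kept, {len(rejections)} rejected")

    stage1 = run_pyronoise(filtered, model, sigma_p=config.sigma_p, cut_p=config.cut_p)
    _log(verbose, "pyronoise", t0, f"{len(stage1.components)} components, "
         f"{stage1.state.n_iter} iterations")

    ws = [
        WeightedSequence(id=f"den{str(j).zfill(4)}", seq=comp.sequence, weight=comp.abundance)
        for j, comp in enumerate(stage1.components)
    ]
    stage2 = run_seqnoise(
        ws, tm, sigma_s=config.sigma_s, cut_s=config.cut_s, truncate_len=config.base_truncation
    )
    _log(verbose, "seqnoise", t0, f"{len(stage2.sequences)} sequences")

    report = run_perseus(
        stage2.sequences,
        tm,
        LogisticModel(alpha=config.alpha, beta=config.beta),
        dist_threshold=config.dist_threshold,
    )
    calls = {c.query_id: c.call for c in report}
    good = [s for s in stage2.sequences if calls[s.id] == "good"]
    _log(verbose, "perseus", t0,
         f"{sum(1 for c in report if c.call == 'chimeric')} chimeric, {len(good)} good")

    rows = []
    for r in rejections:
        rows.append({"read_id": r.read_id, "fate": f"rejected:{r.reason}",
                     "stage1_component": None, "denoised_id": None, "chimera_call": None})
    s2_ids = [s.id for s in stage2.sequences]
    for fg in filtered:
        c1 = stage1.mapping[fg.read_id]
        s1_id = f"den{str(c1).zfill(4)}"
        c2 = stage2.mapping[s1_id]
        den_id = s2_ids[c2]
        rows.append({"read_id": fg.read_id, "fate": "denoised",
                     "stage1_component": s1_id, "denoised_id": den_id,
                     "chimera_call": calls[den_id]})
    provenance = pd.DataFrame(rows)
    return PipelineResult(
        filtered=filtered,
        rejections=rejections,
        stage1=stage1,
        stage2=stage2,
        chimera_report=report,
        good_sequences=good,
        provenance=provenance,
    )
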