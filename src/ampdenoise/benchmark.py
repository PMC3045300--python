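"""The desk-scale synthetic benchmark: one seeded run of the whole pipeline
with every headline metric computed against ground truth.

Study conditions: 20 random 300 bp templates in even proportions, 2000 reads,
30 PCR cycles at the measured per-cycle substitution rates, 5% chimeric
reads, flow noise from the parametric intensity model, GS FLX geometry
(400 raw flows, truncation at 360 flows / 220 bp).  Metrics:

* exact recovery of reference sequences after both denoising stages;
* per-base error rate of raw vs denoised reads (non-chimeric reads only, so
  the number isolates substitution/indel noise rather than splice artifacts);
* chimera sensitivity and parent false positives of the abundance-aware
  classifier, per injected chimera species;
* 3% OTU count after removing reference-classified chimeras, compared with
  the reference OTU count — the published OTU-accuracy procedure.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ChimeraClass, classify_vs_reference, cluster_otus, per_base_error_rate
from .flowgrams import flows_to_sequence
from .pipeline import PipelineConfig, run_pipeline
from .simulate import MockCommunity, random_references, simulate_amplicon_pool, simulate_flowgrams

__all__ = ["run_benchmark"]


def run_benchmark(
    seed: int = 101,
    n_refs: int = 20,
    n_reads: int = 2000,
    chimera_rate: float = 0.05,
    ref_length: int = 300,
    truncate: int = 220,
    verbose: bool = False,
) -> dict:
    """Generate, denoise, and score one synthetic mock community."""
    refs = random_references(n_refs, length=ref_length, seed=seed)
    mc = MockCommunity(
        references=refs,
        abundances=np.full(n_refs, 1.0 / n_refs),
        seed=seed,
        n_reads=n_reads,
        chimera_rate=chimera_rate,
    )
    reads = simulate_amplicon_pool(mc)
    flows = simulate_flowgrams([(r.read_id, r.seq) for r in reads], seed=seed + 1)
    result = run_pipeline(flows, PipelineConfig(), verbose=verbose)

    truth = {r.read_id: r for r in reads}
    prov = result.provenance[result.provenance.fate == "denoised"]
    den_map = {s.id: s.seq for s in result.stage2.sequences}
    calls = {c.query_id: c.call for c in result.chimera_report}

    # reference recovery: each template's analysed prefix present verbatim
    good_seqs = {s.seq for s in result.good_sequences}
    ref_prefixes = [r[:truncate] for r in refs]
    recovered = sum(1 for r in ref_prefixes if r in good_seqs)

    # chimera sensitivity per injected species that survived to stage two
    species_outputs: dict[str, set[str]] = {}
    for rid, did in zip(prov.read_id, prov.denoised_id):
        r = truth[rid]
        if r.is_chimera:
            species_outputs.setdefault(r.origin, set()).add(did)
    flagged = sum(
        1 for outs in species_outputs.values() if any(calls[d] == "chimeric" for d in outs)
    )
    seq_to_id = {s.seq: s.id for s in result.stage2.sequences}
    parent_fp = sum(
        1 for r in ref_prefixes if r in seq_to_id and calls[seq_to_id[r]] == "chimeric"
    )

    # OTU accuracy: drop reference-classified chimeras, rebuild 3% OTUs
    chimera_labels = {
        ChimeraClass.BIMERA,
        ChimeraClass.TRIMERA,
        ChimeraClass.QUADRAMERA,
    }
    kept = [
        (s.id, s.seq)
        for s in result.stage2.sequences
        if classify_vs_reference(s.seq, ref_prefixes).label not in chimera_labels
    ]
    otu_count = len(cluster_otus(kept, cutoffs=[3.0])[0].clusters)
    ref_otus = len(
        cluster_otus(
            [(f"ref{i}", r) for i, r in enumerate(ref_prefixes)], cutoffs=[3.0]
        )[0].clusters
    )

    # per-base error rates on non-chimeric reads, called sequences vs templates
    called = {
        fg.read_id: flows_to_sequence(fg.to_perfect())[:truncate] for fg in result.filtered
    }
    keep_rows = [
        (rid, did) for rid, did in zip(prov.read_id, prov.denoised_id)
        if not truth[rid].is_chimera
    ]
    raw_seqs = [called[rid] for rid, _ in keep_rows]
    mapped = [den_map[did] for _, did in keep_rows]
    raw_rate = per_base_error_rate(raw_seqs, ref_prefixes)
    den_rate = per_base_error_rate(raw_seqs, ref_prefixes, mapped=mapped)

    ll = np.asarray(result.stage1.state.ll_trace)
    return {
        "n_reads": n_reads,
        "n_filtered": len(result.filtered),
        "n_refs": n_refs,
        "recovered_refs": recovered,
        "recovery_percent": 100.0 * recovered / n_refs,
        "chimera_species": len(species_outputs),
        "chimera_species_flagged": flagged,
        "chimera_sensitivity_percent": (
            100.0 * flagged / len(species_outputs) if species_outputs else float("nan")
        ),
        "parent_false_positives": parent_fp,
        "otu_count_3pct": otu_count,
        "ref_otu_count_3pct": ref_otus,
        "raw_error_rate_percent": raw_rate,
        "denoised_error_rate_percent": den_rate,
        "stage1_ll_min_increase": float(np.diff(ll).min()) if len(ll) > 1 else 0.0,
        "result": result,
    }
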