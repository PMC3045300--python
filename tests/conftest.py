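import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tm():
    from ampdenoise.seqnoise import TransitionModel

    return TransitionModel.default()


@pytest.fixture(scope="session")
def intensity_model():
    from ampdenoise.intensity import default_intensity_model

    return default_intensity_model()


@pytest.fixture(scope="session")
def point_mass_model():
    """Intensity model where every run length emits exactly its own integer."""
    from ampdenoise.intensity import model_from_probs

    n_bins, max_run = 1000, 9
    probs = np.zeros((n_bins, max_run + 1))
    for n in range(max_run + 1):
        probs[int(n / 0.01), n] = 1.0
    return model_from_probs(probs)


def write_sff(path, flowgrams):
    """Write Flowgram objects to a real SFF file via Biopython (test fixture)."""
    from Bio.Seq import Seq
    from Bio.SeqIO.SffIO import SffWriter
    from Bio.SeqRecord import SeqRecord

    from ampdenoise.flowgrams import flows_to_sequence

    records = []
    for fg in flowgrams:
        pf = fg.to_perfect()
        seq = flows_to_sequence(pf)
        rec = SeqRecord(Seq(seq), id=fg.read_id)
        rec.annotations["flow_values"] = [int(round(v * 100)) for v in fg.values]
        index = []
        prev = 0
        for i, run in enumerate(pf.runs):
            for _ in range(int(run)):
                index.append(i + 1 - prev)
                prev = i + 1
        rec.annotations["flow_index"] = index
        rec.annotations["flow_chars"] = fg.flow_order * (len(fg.values) // len(fg.flow_order))
        rec.annotations["flow_key"] = "TCAG"
        for k in ("clip_qual_left", "clip_qual_right", "clip_adapter_left", "clip_adapter_right"):
            rec.annotations[k] = 0
        rec.annotations["molecule_type"] = "DNA"
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    with open(path, "wb") as fh:
        SffWriter(fh).write_file(records)
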