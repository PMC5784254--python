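"""Shared fixtures: the benchmark proteome is generated once per session."""

import pytest

from gpcrmine import motif as motif_mod
from gpcrmine import profiles, synthetic, topology

PRESET_SEED = 42


@pytest.fixture(scope="session")
def preset():
    """(records, truth) for the packaged benchmark preset."""
    specs, n_background = synthetic.pinf_like_specs()
    return synthetic.generate_proteome(
        specs, n_background, seed=PRESET_SEED, species="Pinfsim")


@pytest.fixture(scope="session")
def profile_set():
    return profiles.load_default_profiles()


@pytest.fixture(scope="session")
def default_motif_model():
    return motif_mod.build_default_motif_model()


@pytest.fixture(scope="session")
def preset_analysis(preset, profile_set, default_motif_model):
    """Topology, hits and motif presence for every preset record."""
    records, truth = preset
    out = {}
    for r in records:
        topo = topology.predict_topology(r.seq)
        hits = sorted(
            (h for p in profile_set.values()
             for h in profiles.scan_profile(r.seq, p)),
            key=lambda h: h.start,
        )
        motif_hits = motif_mod.scan_motif(r.seq, default_motif_model)
        out[r.id] = {"topology": topo, "hits": hits, "motif_hits": motif_hits}
    return out
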