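import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from genevote import ExpressionGroup, ProbeAnnotation


def make_group(case, control, group_id="g1", disease="T2DM",
               tissue="skeletal muscle", platform="PLATX",
               probe_ids=None) -> ExpressionGroup:
    """Build a validated group from case/control matrices (probes x samples)."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n_probes = case.shape[0]
    if probe_ids is None:
        probe_ids = tuple(f"p{i + 1}" for i in range(n_probes))
    cs = tuple(f"c{i + 1}" for i in range(case.shape[1]))
    ks = tuple(f"k{i + 1}" for i in range(control.shape[1]))
    return ExpressionGroup(
        group_id=group_id, disease_label=disease, tissue=tissue,
        platform_id=platform, probe_ids=tuple(probe_ids),
        sample_ids=cs + ks, values=np.hstack([case, control]),
        case_samples=cs, control_samples=ks)


@pytest.fixture
def tiny_group():
    """4 probes x (3 case + 3 control), two genes with two probes each."""
    rng = np.random.default_rng(7)
    return make_group(rng.normal(7, 1, (4, 3)), rng.normal(7, 1, (4, 3)))


@pytest.fixture
def tiny_annotation():
    return ProbeAnnotation("PLATX", {
        "p1": frozenset({"GENE_A"}), "p2": frozenset({"GENE_A"}),
        "p3": frozenset({"GENE_B"}), "p4": frozenset({"GENE_B"})})
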