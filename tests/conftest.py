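import numpy as np
import pytest

from countperm.datatypes import CONTROL, TREATED, ExpressionMatrix


def make_expr(intensities, n_control, n_treated, probe_ids=None):
    intensities = np.asarray(intensities, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(intensities.shape[0])]
    sample_ids = [f"C{k}" for k in range(n_control)] + [
        f"T{k}" for k in range(n_treated)
    ]
    group_of = {s: CONTROL for s in sample_ids[:n_control]}
    group_of.update({s: TREATED for s in sample_ids[n_control:]})
    return ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        intensities=intensities,
        group_of=group_of,
    )


@pytest.fixture
def tiny_expr():
    """3 probes x 4 samples (2 control, 2 treated)."""
    return make_expr(
        [[10, 10, 20, 20], [5, 5, 5, 5], [8, 12, 30, 2]],
        n_control=2,
        n_treated=2,
    )


@pytest.fixture
def five_five_expr():
    """1 probe, clean 2-fold induction in all five treated samples."""
    return make_expr([[100] * 5 + [200] * 5], n_control=5, n_treated=5)
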