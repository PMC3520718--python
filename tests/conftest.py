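import numpy as np
import pandas as pd
import pytest

from prr import diffexpr, simulate


@pytest.fixture(scope="session")
def small_study():
    """300-gene study at the default noise level (shared, read-only)."""
    return simulate.simulate_study(300, d=2.0, noise_sd=0.25, n_reps=3, seed=11)


@pytest.fixture(scope="session")
def small_root_calls(small_study):
    from prr import response_recovery as rr

    expr, design, truth = small_study
    resp = diffexpr.compute_contrast(expr, design, "root", "response")
    rec = diffexpr.compute_contrast(expr, design, "root", "recovery")
    return rr.classify_organ(resp, rec), truth


def make_calls(class_counts: dict[str, int], organ: str, prefix: str = "G") -> pd.DataFrame:
    """Build a synthetic call table with exact per-class counts."""
    codes = [c for c, n in class_counts.items() for _ in range(n)]
    idx = pd.Index([f"{prefix}{i:06d}" for i in range(len(codes))], name="gene_id")
    return pd.DataFrame({"organ": organ, "class_code": codes, "alpha": 0.001}, index=idx)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
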