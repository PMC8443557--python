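import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def match_events(detected_s: np.ndarray, planted_s: np.ndarray,
                 tol_s: float = 0.005) -> int:
    """Greedy one-to-one matching of detected to planted event times."""
    used = np.zeros(detected_s.size, dtype=bool)
    matched = 0
    for t in planted_s:
        cand = np.where((np.abs(detected_s - t) <= tol_s) & ~used)[0]
        if cand.size:
            used[cand[np.argmin(np.abs(detected_s[cand] - t))]] = True
            matched += 1
    return matched


@pytest.fixture
def small_call_table():
    return pd.DataFrame({
        "onset_s": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0],
        "call_type": ["phee"] * 4 + ["trill"] * 4 + ["twitter"] * 2,
    })
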