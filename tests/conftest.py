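import numpy as np
import pytest

from napusmap.binning import ScoringMatrix, encode_calls


def matrix_from_strings(strings: dict[str, str], groups: dict[str, str] | None = None,
                        missing_char: str = "-") -> ScoringMatrix:
    """Build a ScoringMatrix from {marker_id: scoring_string}."""
    marker_ids = list(strings)
    n_lines = len(next(iter(strings.values())))
    calls = np.vstack([encode_calls(strings[m], missing_char) for m in marker_ids])
    return ScoringMatrix(
        marker_ids=marker_ids,
        line_ids=[f"L{i + 1:03d}" for i in range(n_lines)],
        calls=calls,
        linkage_groups=[groups[m] for m in marker_ids] if groups else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
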