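import numpy as np
import pytest

from imrf import ExpressionMatrix, LabelVector


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        sample_ids=[f"s{i}" for i in range(6)],
        feature_names=["f1", "f2", "f3"],
        values=rng.normal(size=(6, 3)),
    )


@pytest.fixture
def toy_labels(toy_matrix) -> LabelVector:
    return LabelVector.from_labels(["A", "A", "A", "B", "B", "B"])


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)
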