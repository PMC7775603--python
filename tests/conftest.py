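import io

import numpy as np
import pandas as pd
import pytest

from pcmphylo.matrix import ParameterMatrix, read_matrix


@pytest.fixture
def toy_matrix() -> ParameterMatrix:
    """4 languages x 3 parameters covering all four states."""
    csv = "lang,p1,p2,p3\nA,+,-,0\nB,+,+,-\nC,-,+,+\nD,-,-,?\n"
    return read_matrix(io.StringIO(csv))


@pytest.fixture
def split_matrix() -> ParameterMatrix:
    """Every column perfectly splits {A,B} from {C,D}."""
    row_ab = ["+", "+", "+", "-", "-", "-"]
    row_cd = ["-", "-", "-", "+", "+", "+"]
    data = pd.DataFrame(
        [row_ab, row_ab, row_cd, row_cd],
        index=["A", "B", "C", "D"],
        columns=[f"p{i}" for i in range(1, 7)],
    )
    return ParameterMatrix(data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def random_matrix(rng, n_lang, n_par, p_null=0.2, p_unknown=0.0) -> ParameterMatrix:
    syms = rng.choice(
        ["+", "-", "0", "?"],
        p=[(1 - p_null - p_unknown) / 2, (1 - p_null - p_unknown) / 2, p_null, p_unknown],
        size=(n_lang, n_par),
    )
    return ParameterMatrix(pd.DataFrame(
        syms, index=[f"L{i:02d}" for i in range(n_lang)],
        columns=[f"p{j}" for j in range(n_par)],
    ))
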