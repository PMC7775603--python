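"""Access to the published 69-language × 94-parameter study matrix.

The matrix itself is third-party research data published as supplementary
material of the original study (tables FS1/TS1, also in the study's public
data deposit) and is not redistributed inside this package.  Place the CSV
(languages as rows or parameters as rows) at ``data/study_matrix.csv``
relative to your working directory, or pass an explicit path.
"""

from __future__ import annotations

from pathlib import Path

from .matrix import ParameterMatrix, read_matrix

__all__ = ["load_study_matrix", "DEFAULT_STUDY_MATRIX_PATHS"]

DEFAULT_STUDY_MATRIX_PATHS = (
    Path("data/study_matrix.csv"),
    Path("study_matrix.csv"),
)


def load_study_matrix(path: str | Path | None = None) -> ParameterMatrix:
    """Load the deposited 69×94 parameter matrix.

    Tries both file orientations and returns the one with 69 language rows
    and 94 parameter columns.  Raises FileNotFoundError with download
    instructions if the file is absent.
    """
    candidates = [Path(path)] if path is not None else [p for p in DEFAULT_STUDY_MATRIX_PATHS]
    found = next((p for p in candidates if p.exists()), None)
    if found is None:
        raise FileNotFoundError(
            "study matrix not found (looked at: "
            + ", ".join(str(p) for p in candidates)
            + "). Obtain the 69-language x 94-parameter table from the "
            "original study's supplementary material (tables FS1/TS1, also "
            "in its public data deposit) and save it as CSV at "
            "data/study_matrix.csv."
        )
    m = read_matrix(found, orientation="languages-as-rows")
    if m.n_languages > m.n_parameters:
        # languages are the shorter axis (69 < 94): the file must have had
        # parameters as rows
        m = read_matrix(found, orientation="parameters-as-rows")
    if (m.n_languages, m.n_parameters) != (69, 94):
        raise ValueError(
            f"expected a 69-language x 94-parameter matrix, got "
            f"{m.n_languages} x {m.n_parameters} from {found}"
        )
    return m
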