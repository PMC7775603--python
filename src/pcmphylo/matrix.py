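"""Three-state syntactic parameter matrices: reading, validation, summaries, recoding.

The central object is :class:`ParameterMatrix`, a languages × parameters grid
whose cells are one of four states:

``+``
    the marked value of a parameter, set from positive evidence;
``-``
    the default value (assumed absent positive evidence);
``0``
    the *null* state: the parameter is irrelevant/predictable given the
    states of other parameters (implicational structure), so the cell carries
    no independent information;
``?``
    not observed.

Null and unknown cells are excluded from every pairwise comparison downstream;
they are tracked separately in summaries because they arise for different
reasons (deducible vs. missing).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLUS",
    "MINUS",
    "NULL",
    "UNKNOWN",
    "STATES",
    "Dependency",
    "ParameterDefinition",
    "LanguageRecord",
    "ParameterMatrix",
    "SummaryReport",
    "DependencyViolation",
    "read_matrix",
    "write_matrix",
    "matrix_summary",
    "validate_dependencies",
    "nexus_export",
]

PLUS = "+"
MINUS = "-"
NULL = "0"
UNKNOWN = "?"
STATES = (PLUS, MINUS, NULL, UNKNOWN)

# integer codes used for vectorized computation
CODE = {PLUS: 1, MINUS: 0, NULL: -1, UNKNOWN: -2}
SYMBOL = {v: k for k, v in CODE.items()}

# accepted spellings on input (various Unicode minus/dash glyphs)
DEFAULT_ALIASES = {
    "+": PLUS,
    "-": MINUS,
    "−": MINUS,  # minus sign
    "–": MINUS,  # en dash
    "—": MINUS,  # em dash
    "0": NULL,
    "?": UNKNOWN,
}


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files (bad symbols, ragged rows, duplicates)."""


@dataclass(frozen=True)
class Dependency:
    """Condition under which a parameter is defined.

    ``terms`` is a sequence of ``(parameter_code, required_state)`` pairs with
    ``required_state`` in {``+``, ``-``}; ``mode`` says whether all terms must
    hold (conjunction) or any one suffices (disjunction).
    """

    terms: tuple[tuple[str, str], ...]
    mode: Literal["all", "any"] = "all"

    def __post_init__(self) -> None:
        for code, state in self.terms:
            if state not in (PLUS, MINUS):
                raise ValueError(
                    f"dependency on {code!r} requires state {state!r}; "
                    f"only '+' or '-' are meaningful conditions"
                )

    def is_met(self, states: dict[str, str]) -> bool:
        """Evaluate against a mapping of parameter code -> observed state.

        A term referencing a parameter that is itself NULL or UNKNOWN is unmet.
        """
        results = [states.get(code) == state for code, state in self.terms]
        return all(results) if self.mode == "all" else any(results)


@dataclass(frozen=True)
class ParameterDefinition:
    """One syntactic parameter: ordinal position, short code, optional condition."""

    ordinal: int
    code: str
    label: str = ""
    dependency: Dependency | None = None


@dataclass(frozen=True)
class LanguageRecord:
    """A taxon: unique name plus optional family/subgroup labels."""

    name: str
    family: str | None = None
    subgroup: str | None = None


@dataclass
class ParameterMatrix:
    """Languages × parameters grid over {+, -, 0, ?}.

    ``data`` holds canonical single-character strings; ``codes`` exposes the
    same grid as an int8 array (+1, 0, -1, -2) for vectorized computation.
    """

    data: pd.DataFrame
    definitions: list[ParameterDefinition] | None = None
    language_records: list[LanguageRecord] | None = None

    def __post_init__(self) -> None:
        bad = ~self.data.isin(STATES)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise MatrixFormatError(
                f"invalid state {self.data.iat[r, c]!r} at language "
                f"{self.data.index[r]!r}, parameter {self.data.columns[c]!r}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate language labels: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate parameter labels: {dups}")

    # -- basic accessors ---------------------------------------------------

    @property
    def languages(self) -> list[str]:
        return list(self.data.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_languages(self) -> int:
        return self.data.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.data.shape[1]

    @property
    def codes(self) -> np.ndarray:
        """Int8 view: +1 plus, 0 minus, -1 null, -2 unknown."""
        arr = self.data.to_numpy(dtype="U1")
        codes = np.full(arr.shape, CODE[UNKNOWN], dtype=np.int8)
        codes[arr == PLUS] = CODE[PLUS]
        codes[arr == MINUS] = CODE[MINUS]
        codes[arr == NULL] = CODE[NULL]
        return codes

    def row_codes(self, language: str) -> np.ndarray:
        i = self.data.index.get_loc(language)
        return self.codes[i]

    def subset(self, languages: Sequence[str]) -> "ParameterMatrix":
        return ParameterMatrix(self.data.loc[list(languages)].copy(),
                               definitions=self.definitions)

    def resample_columns(self, rng: np.random.Generator) -> "ParameterMatrix":
        """Character bootstrap: sample the parameter columns with replacement."""
        idx = rng.integers(0, self.n_parameters, size=self.n_parameters)
        boot = self.data.iloc[:, idx].copy()
        boot.columns = [f"b{i}" for i in range(self.n_parameters)]
        return ParameterMatrix(boot)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterMatrix) and self.data.equals(other.data)


# -- IO ---------------------------------------------------------------------


def _canonicalize(token: str, aliases: dict[str, str]) -> str | None:
    return aliases.get(token.strip())


def read_matrix(
    path_or_buffer,
    orientation: Literal["languages-as-rows", "parameters-as-rows"] = "languages-as-rows",
    delimiter: str | None = None,
    aliases: dict[str, str] | None = None,
) -> ParameterMatrix:
    """Read a delimiter-separated character matrix.

    The file must have one header row and one label column; cells are drawn
    from the accepted symbol aliases (``+``; ``-`` and Unicode dashes; ``0``;
    ``?``).  ``orientation`` states what the file's *rows* are; the returned
    matrix is always languages-as-rows.

    Raises :class:`MatrixFormatError` naming the offending cell for unknown
    symbols, and for ragged rows or duplicated labels.
    """
    aliases = dict(DEFAULT_ALIASES if aliases is None else aliases)
    if delimiter is None:
        # sniff between comma and tab on the header line
        if hasattr(path_or_buffer, "read"):
            text = path_or_buffer.read()
        else:
            with open(path_or_buffer, "r", encoding="utf-8") as fh:
                text = fh.read()
        header = text.splitlines()[0] if text else ""
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
        path_or_buffer = io.StringIO(text)
    try:
        df = pd.read_csv(path_or_buffer, sep=delimiter, index_col=0, dtype=str,
                         keep_default_na=False, skipinitialspace=True)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise MatrixFormatError(f"malformed matrix file: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if orientation == "parameters-as-rows":
        df = df.T
    elif orientation != "languages-as-rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    canon = df.copy()
    for j, col in enumerate(df.columns):
        mapped = df[col].map(lambda t: _canonicalize(t, aliases))
        if mapped.isna().any():
            i = int(np.argmax(mapped.isna().to_numpy()))
            raise MatrixFormatError(
                f"unknown symbol {df[col].iloc[i]!r} at language "
                f"{df.index[i]!r}, parameter {col!r}"
            )
        canon[col] = mapped
    return ParameterMatrix(canon)


def write_matrix(
    m: ParameterMatrix,
    path,
    orientation: Literal["languages-as-rows", "parameters-as-rows"] = "languages-as-rows",
    delimiter: str = ",",
) -> None:
    """Write the matrix as delimited text; inverse of :func:`read_matrix`."""
    df = m.data if orientation == "languages-as-rows" else m.data.T
    df.to_csv(path, sep=delimiter)


# -- summaries ---------------------------------------------------------------


@dataclass
class SummaryReport:
    """Exhaustive cell counts and per-language / per-pair support statistics."""

    n_languages: int
    n_parameters: int
    n_cells: int
    n_null: int
    n_plus: int
    n_minus: int
    n_unknown: int
    plus_per_language: pd.Series
    mean_plus: float
    median_plus: float
    pair_overlap: pd.DataFrame  # symmetric counts of mutually non-null parameters
    mean_overlap: float
    min_overlap: int
    max_overlap: int

    def rounded(self) -> dict:
        """Headline numbers at the integer precision used in reports."""
        return {
            "n_cells": self.n_cells,
            "n_null": self.n_null,
            "n_plus": self.n_plus,
            "n_minus": self.n_minus,
            "n_unknown": self.n_unknown,
            "mean_plus": round(self.mean_plus),
            "median_plus": round(self.median_plus),
            "mean_overlap": round(self.mean_overlap),
            "min_overlap": self.min_overlap,
            "max_overlap": self.max_overlap,
        }

    def to_frame(self) -> pd.DataFrame:
        d = self.rounded()
        d.update(n_languages=self.n_languages, n_parameters=self.n_parameters)
        return pd.DataFrame({"value": pd.Series(d)})


def matrix_summary(m: ParameterMatrix) -> SummaryReport:
    """Count cell states and compute per-pair non-null overlap.

    Overlap for a language pair is the number of parameters that are
    informative (``+`` or ``-``) in *both* languages — the effective number of
    taxonomic characters available for that comparison.
    """
    if m.n_languages == 0 or m.n_parameters == 0:
        raise ValueError("empty matrix")
    codes = m.codes
    n_cells = codes.size
    n_plus = int((codes == 1).sum())
    n_minus = int((codes == 0).sum())
    n_null = int((codes == -1).sum())
    n_unknown = int((codes == -2).sum())
    plus_per_lang = pd.Series((codes == 1).sum(axis=1), index=m.languages, name="n_plus")

    defined = (codes >= 0).astype(np.int64)
    overlap = defined @ defined.T
    ov = pd.DataFrame(overlap, index=m.languages, columns=m.languages)
    iu = np.triu_indices(m.n_languages, k=1)
    off = overlap[iu]
    return SummaryReport(
        n_languages=m.n_languages,
        n_parameters=m.n_parameters,
        n_cells=n_cells,
        n_null=n_null,
        n_plus=n_plus,
        n_minus=n_minus,
        n_unknown=n_unknown,
        plus_per_language=plus_per_lang,
        mean_plus=float(plus_per_lang.mean()),
        median_plus=float(plus_per_lang.median()),
        pair_overlap=ov,
        mean_overlap=float(off.mean()) if off.size else float("nan"),
        min_overlap=int(off.min()) if off.size else 0,
        max_overlap=int(off.max()) if off.size else 0,
    )


# -- dependency validation ---------------------------------------------------


@dataclass(frozen=True)
class DependencyViolation:
    language: str
    parameter: str
    observed: str
    condition_met: bool

    def __str__(self) -> str:
        expected = "defined (+/-)" if self.condition_met else "null (0)"
        return (f"{self.language}/{self.parameter}: observed {self.observed!r} "
                f"but condition {'met' if self.condition_met else 'unmet'} "
                f"implies {expected}")


def _check_dependency_graph(defs: Iterable[ParameterDefinition]) -> None:
    codes = {d.code for d in defs}
    adj: dict[str, set[str]] = {d.code: set() for d in defs}
    for d in defs:
        if d.dependency is None:
            continue
        for ref, _ in d.dependency.terms:
            if ref not in codes:
                raise ValueError(f"dependency of {d.code!r} references unknown code {ref!r}")
            adj[d.code].add(ref)
    # DFS cycle detection
    state: dict[str, int] = {}

    def visit(u: str, stack: list[str]) -> None:
        state[u] = 1
        for v in adj[u]:
            if state.get(v) == 1:
                raise ValueError(f"cyclic dependencies: {' -> '.join(stack + [u, v])}")
            if state.get(v, 0) == 0:
                visit(v, stack + [u])
        state[u] = 2

    for c in codes:
        if state.get(c, 0) == 0:
            visit(c, [])


def validate_dependencies(
    m: ParameterMatrix,
    defs: Sequence[ParameterDefinition],
) -> list[DependencyViolation]:
    """Check every cell against the declared implicational structure.

    A violation is a cell that is NULL while its defining condition is met, or
    informative (+/-) while the condition is unmet.  Parameters without a
    declared dependency are unconstrained.  An empty list means the matrix's
    null pattern is fully consistent with the declared implications.
    """
    _check_dependency_graph(defs)
    by_code = {d.code: d for d in defs}
    violations: list[DependencyViolation] = []
    for lang in m.languages:
        states = m.data.loc[lang].to_dict()
        for p in m.parameters:
            d = by_code.get(p)
            if d is None or d.dependency is None:
                continue
            met = d.dependency.is_met(states)
            obs = states[p]
            if obs == UNKNOWN:
                continue  # unobserved cells assert nothing
            if met and obs == NULL:
                violations.append(DependencyViolation(lang, p, obs, True))
            elif not met and obs in (PLUS, MINUS):
                violations.append(DependencyViolation(lang, p, obs, False))
    return violations


# -- NEXUS export ------------------------------------------------------------


def _nexus_safe(label: str) -> str:
    if any(ch in label for ch in " ()[]{}/\\,;:=*'\"`+-<>"):
        return "'" + label.replace("'", "''") + "'"
    return label


def nexus_export(m: ParameterMatrix) -> str:
    """Recode for character-based tools: + -> 1, - -> 0, null/unknown -> ?.

    The null states carry no independent information, so they are written as
    missing characters, letting downstream algorithms ignore them rather than
    treating "0" as a third observed value.
    """
    if m.n_languages == 0 or m.n_parameters == 0:
        raise ValueError("empty matrix")
    recode = {PLUS: "1", MINUS: "0", NULL: "?", UNKNOWN: "?"}
    width = max(len(_nexus_safe(l)) for l in m.languages)
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={m.n_languages} NCHAR={m.n_parameters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for lang in m.languages:
        row = "".join(recode[s] for s in m.data.loc[lang])
        lines.append(f"    {_nexus_safe(lang):<{width}}  {row}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def nexus_import(text: str) -> ParameterMatrix:
    """Read back a standard-data NEXUS matrix (1 -> +, 0 -> -, ? -> unknown).

    The null/unknown distinction is not representable in NEXUS, so all ``?``
    come back as UNKNOWN.
    """
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.strip().upper() == "MATRIX")
    except StopIteration:
        raise MatrixFormatError("no MATRIX block found") from None
    rows: dict[str, str] = {}
    for line in lines[start + 1:]:
        s = line.strip()
        if s == ";" or s.upper().startswith("END"):
            break
        if not s:
            continue
        if s.startswith("'"):
            end = s.index("'", 1)
            label, chars = s[1:end], s[end + 1:].strip()
        else:
            label, _, chars = s.partition(" ")
            chars = chars.strip()
        rows[label] = chars.replace(" ", "")
    recode = {"1": PLUS, "0": MINUS, "?": UNKNOWN}
    df = pd.DataFrame(
        [[recode[c] for c in chars] for chars in rows.values()],
        index=list(rows.keys()),
        columns=[f"p{i+1}" for i in range(len(next(iter(rows.values()))))],
    )
    return ParameterMatrix(df)
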