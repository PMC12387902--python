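"""Cohort table loading, validation, description and scaling.

The analysis operates on a small clinical cohort table: one row per
subject, one column per Rorschach coding variable (localization,
determinant, content, popular/original, resonance-type and
particular-phenomena counts), plus a diagnostic group label
(``AD`` for Alzheimer dementia, ``INPH`` for idiopathic normal
pressure hydrocephalus).  All variables are non-negative integers;
many of the particular-phenomena columns are 0/1 flags.

A reference cohort of 19 subjects and 45 variables is bundled with the
package and can be loaded with :func:`load_fixture`.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("AD", "INPH")

#: Canonical variable order of the bundled cohort (Italian column headers).
TABLE_VARIABLES = [
    "Numero Risposte", "G", "D", "Dd", "DG",
    "F", "F+", "F-", "M", "FM", "m", "CF", "Fcho", "CHO",
    "BAN", "ORIG", "ORIG+",
    "A", "Ad", "U", "(u)", "Ud", "Obj", "Cibo", "Nat", "Bot", "Anat",
    "Fumo", "Cartoon", "Art",
    "IR", "TRI I", "TRI II",
    "Perseverazioni", "Inadeguatezza", "Insicurezza", "Stereotipie",
    "Rifiuti", "Confabulazione", "Astrazione", "Contaminazione",
    "Diff. Denominazione", "Autoriferimento", "Devitalizzazione",
    "Sensazione",
]

#: English display names for the Italian table headers.
ENGLISH_NAMES = {
    "Numero Risposte": "Number of answers",
    "G": "Global (G)",
    "D": "Details (D)",
    "Dd": "Little details (Dd)",
    "DG": "Details to global (DG)",
    "F": "F (shape)",
    "F+": "F+ (positive shape)",
    "F-": "F- (negative shape)",
    "M": "M (human kinesthetic activity)",
    "FM": "FM (animal kinesthetic activity)",
    "m": "m (inanimate movement)",
    "CF": "CF (color-form)",
    "Fcho": "FCho (diffuse shading)",
    "CHO": "Cho (pure shading)",
    "BAN": "Popular",
    "ORIG": "Original",
    "ORIG+": "Original with good form",
    "A": "A (animals)",
    "Ad": "Ad (animal details)",
    "U": "H (human)",
    "(u)": "(H) (fantastic human)",
    "Ud": "Hd (human details)",
    "Obj": "Object",
    "Cibo": "Food",
    "Nat": "Nature",
    "Bot": "Botanic",
    "Anat": "Anatomical",
    "Fumo": "Smoke",
    "Cartoon": "Cartoon",
    "Art": "Art",
    "IR": "IR (reality index)",
    "TRI I": "TRI I (Erlebnistypus I)",
    "TRI II": "TRI II (Erlebnistypus II)",
    "Perseverazioni": "Perseveration",
    "Inadeguatezza": "Inadequacy",
    "Insicurezza": "Insecurity",
    "Stereotipie": "Stereotyped",
    "Rifiuti": "Refuse",
    "Confabulazione": "Confabulation",
    "Astrazione": "Abstraction",
    "Contaminazione": "Contamination",
    "Diff. Denominazione": "Difficulty of naming",
    "Autoriferimento": "Self-reference",
    "Devitalizzazione": "Devitalization",
    "Sensazione": "Sensation",
}

#: Names of the binary group-indicator columns appended for association
#: learning (one per diagnostic group).
INDICATOR_NAMES = ("INPH", "DEMENZA")


class CohortError(ValueError):
    """Raised for malformed cohort input."""


@dataclass
class CohortTable:
    """Subjects x variables table of non-negative integer codings.

    Attributes
    ----------
    subject_ids : list of str
        Unique subject labels, e.g. ``"Demenza 1"``, ``"INPH 7 pr"``.
    groups : list of str
        Per-subject diagnostic group, each in :data:`GROUPS`.
    variable_names : list of str
        Ordered variable names (column order is meaningful).
    values : ndarray of shape (n_subjects, n_variables)
        Non-negative integer codings.
    """

    subject_ids: list[str]
    groups: list[str]
    variable_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if len(self.subject_ids) != n or len(self.groups) != n:
            raise CohortError("subject_ids/groups length does not match values")
        if len(self.variable_names) != p:
            raise CohortError("variable_names length does not match values")
        if len(set(self.subject_ids)) != n:
            raise CohortError("duplicate subject ids")
        if len(set(self.variable_names)) != p:
            raise CohortError("duplicate variable names")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise CohortError(f"unknown group labels: {sorted(unknown)}")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise CohortError("cohort values must be integers")
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            raise CohortError("cohort values must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"no such variable: {name!r}") from None
        return self.values[:, j]

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.groups])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "group", self.groups)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_cohort(path) -> CohortTable:
    """Load a cohort table from CSV.

    The file must have a header row with ``subject_id``, ``group`` and
    then one column per variable.  Missing *trailing* cells in a row
    (a truncated line) are filled with 0 and logged as a warning; a
    blank cell anywhere else, a negative number or a non-integer is a
    parse error naming the offending row and column.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise OSError(f"empty or unreadable CSV file: {path}") from exc
    if df.shape[1] < 3 or list(df.columns[:2]) != ["subject_id", "group"]:
        raise CohortError(
            "CSV must start with 'subject_id' and 'group' columns followed by variables"
        )
    variable_names = list(df.columns[2:])
    subject_ids = df["subject_id"].tolist()
    groups = df["group"].tolist()
    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise CohortError(f"unknown group labels: {sorted(unknown)}")

    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    values = np.zeros(raw.shape, dtype=np.int64)
    n, p = raw.shape
    for i in range(n):
        # pandas fills a truncated line with NaN -> '' under dtype=str;
        # only a *trailing* run of blanks qualifies for the fill-0 rule.
        row = [str(c) for c in raw[i]]
        j_last = p
        while j_last > 0 and row[j_last - 1].strip() in ("", "nan"):
            j_last -= 1
        for j in range(p):
            cell = row[j].strip()
            if j >= j_last:
                if cell in ("", "nan"):
                    logger.warning(
                        "subject %r: missing trailing cell %r filled with 0",
                        subject_ids[i], variable_names[j],
                    )
                    values[i, j] = 0
                    continue
            if cell in ("", "nan"):
                raise CohortError(
                    f"blank cell at subject {subject_ids[i]!r}, "
                    f"variable {variable_names[j]!r}"
                )
            try:
                x = int(cell)
            except ValueError:
                raise CohortError(
                    f"non-integer value {cell!r} at subject {subject_ids[i]!r}, "
                    f"variable {variable_names[j]!r}"
                ) from None
            if x < 0:
                raise CohortError(
                    f"negative value {x} at subject {subject_ids[i]!r}, "
                    f"variable {variable_names[j]!r}"
                )
            values[i, j] = x
    return CohortTable(subject_ids, groups, variable_names, values)


def load_fixture() -> CohortTable:
    """Load the bundled 19-subject, 45-variable reference cohort."""
    text = resources.files("inkmap").joinpath("data/cohort.csv").read_text()
    return load_cohort(io.StringIO(text))


# ---------------------------------------------------------------------------
# Protocol validation

#: Structural coding rules: the response count must decompose over the
#: localization categories and over the determinant categories, and the
#: form count must split into good and poor form.
PROTOCOL_RULES = {
    "localization_sum": ("Numero Risposte", ["G", "D", "Dd", "DG"]),
    "determinant_sum": ("Numero Risposte", ["F", "M", "FM", "m", "CF", "Fcho", "CHO"]),
    "form_split": ("F", ["F+", "F-"]),
}


@dataclass
class ProtocolViolation:
    subject_id: str
    rule: str
    expected: int
    observed: int


@dataclass
class ProtocolValidationReport:
    violations: list[ProtocolViolation]
    summary: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "violations": [vars(v) for v in self.violations],
            "summary": self.summary,
        }


def validate_protocol(table: CohortTable) -> ProtocolValidationReport:
    """Check the structural coding-sum rules on every subject.

    Violations are soft warnings; the report never aborts the pipeline.
    A variable required by a rule that is absent from the table is a
    configuration error.
    """
    for rule, (total, parts) in PROTOCOL_RULES.items():
        for name in [total, *parts]:
            if name not in table.variable_names:
                raise CohortError(f"rule {rule!r} requires missing variable {name!r}")
    violations = []
    summary = {rule: 0 for rule in PROTOCOL_RULES}
    for i, sid in enumerate(table.subject_ids):
        for rule, (total, parts) in PROTOCOL_RULES.items():
            expected = int(table.column(total)[i])
            observed = int(sum(table.column(p)[i] for p in parts))
            if expected != observed:
                violations.append(ProtocolViolation(sid, rule, expected, observed))
                summary[rule] += 1
    return ProtocolValidationReport(violations, summary)


# ---------------------------------------------------------------------------
# Descriptive statistics

@dataclass
class DescriptiveStats:
    """Per-variable mean, sd, min and max (response-count units)."""

    variable_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    ddof: int = 1

    def row(self, name: str) -> dict[str, float]:
        j = self.variable_names.index(name)
        return {
            "mean": float(self.mean[j]),
            "sd": float(self.sd[j]),
            "min": float(self.min[j]),
            "max": float(self.max[j]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd, "min": self.min, "max": self.max},
            index=pd.Index(self.variable_names, name="variable"),
        )

    def to_dict(self, decimals: int = 2) -> dict:
        out = {}
        for name in self.variable_names:
            r = self.row(name)
            out[name] = {k: round(v, decimals) for k, v in r.items()}
        return out


def descriptive_stats(table: CohortTable, ddof: int = 1) -> DescriptiveStats:
    """Compute per-variable mean/sd/min/max.

    The default sd uses the n-1 (sample) denominator, which is the
    convention the reference cohort's published summary follows.
    """
    if table.n_subjects == 0:
        raise CohortError("empty table")
    X = table.values.astype(float)
    sd = X.std(axis=0, ddof=ddof) if table.n_subjects > ddof else np.zeros(X.shape[1])
    return DescriptiveStats(
        list(table.variable_names), X.mean(axis=0), sd,
        X.min(axis=0), X.max(axis=0), ddof=ddof,
    )


# ---------------------------------------------------------------------------
# Min-max scaling

@dataclass
class ScaledMatrix:
    """Column-wise min-max scaled view of a cohort, with inversion info.

    Every entry lies in [0, 1].  Constant columns map to 0 everywhere
    so that they stay inert in downstream association learning.
    """

    values: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    variable_names: list[str]
    subject_ids: list[str]
    groups: list[str]
    source: CohortTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise CohortError("scaled values must lie in [0, 1]")
        self.values = v

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def inverse(self) -> np.ndarray:
        """Map scaled values back to the original integer scale."""
        span = self.maxs - self.mins
        return np.rint(self.values * span + self.mins).astype(np.int64)


def minmax_scale(table: CohortTable) -> ScaledMatrix:
    """Affine per-variable map x -> (x - min) / (max - min).

    Constant variables are mapped to 0 (not 0.5) by convention.
    """
    if table.n_subjects < 2:
        raise CohortError("min-max scaling needs at least 2 subjects")
    X = table.values.astype(float)
    mins, maxs = X.min(axis=0), X.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    scaled = (X - mins) / span
    return ScaledMatrix(
        scaled, mins, maxs, list(table.variable_names),
        list(table.subject_ids), list(table.groups), source=table,
    )


def append_group_indicators(table: CohortTable) -> CohortTable:
    """Return a new table with binary INPH and DEMENZA membership columns.

    The indicators make the diagnostic groups visible to the association
    network as ordinary variables, so group-variable links can be read
    off the learned weight matrix.  Requires both groups to be present
    (otherwise an indicator would be constant) and refuses to run twice.
    """
    present = set(table.groups)
    if present != set(GROUPS):
        raise CohortError(
            f"both groups required to build indicators; found {sorted(present)}"
        )
    clash = set(INDICATOR_NAMES) & set(table.variable_names)
    if clash:
        raise CohortError(f"indicator columns already present: {sorted(clash)}")
    inph = table.group_mask("INPH").astype(np.int64)
    dem = 1 - inph
    values = np.column_stack([table.values, inph, dem])
    return CohortTable(
        list(table.subject_ids), list(table.groups),
        list(table.variable_names) + list(INDICATOR_NAMES), values,
    )
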