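"""Event-by-sample data model shared by every other module.

A cohort is represented three ways:

* a *categorical* matrix ``M`` whose cells hold observation codes (``Z`` for
  wild type; ``HS``/``L``/``S``/``I`` for mutation observations; ``WA``/``SA``
  for amplifications; ``WD``/``SD`` for deletions; a comma-joined set of codes
  for hybrid co-observations such as ``L,WD``),
* a *binary* matrix ``D`` (altered / wild type), and
* a *penalty* matrix ``P`` holding the negative natural log of each altered
  cell's passenger probability (0 on wild-type cells).

``D`` and ``P`` are the pair the optimizer consumes; ``M`` is the probabilistic
representation the penalty builder works from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Single-observation codes, in canonical serialization order.
CODE_ORDER = ("HS", "L", "S", "I", "WA", "SA", "WD", "SD")
WILD_TYPE = "Z"

MUTATION_CODES = frozenset({"HS", "L", "S", "I"})
AMP_CODES = frozenset({"WA", "SA"})
DEL_CODES = frozenset({"WD", "SD"})

EVENT_TYPES = ("mutation", "amplification", "deletion", "mutdel", "mutamp")

#: non-wild-type codes permitted per event type
ALLOWED_CODES = {
    "mutation": MUTATION_CODES,
    "amplification": AMP_CODES,
    "deletion": DEL_CODES,
    "mutdel": MUTATION_CODES | DEL_CODES,
    "mutamp": MUTATION_CODES | AMP_CODES,
}

#: label suffix per event type (e.g. "BRAF-M", "PTEN-MD")
TYPE_SUFFIX = {
    "mutation": "-M",
    "amplification": "-A",
    "deletion": "-D",
    "mutdel": "-MD",
    "mutamp": "-MA",
}

# Only hybrid event types may carry a multi-code co-observation.
HYBRID_TYPES = frozenset({"mutdel", "mutamp"})


class MatrixError(ValueError):
    """Raised on malformed matrices or codes."""


def parse_code(cell: str) -> frozenset[str]:
    """Parse a serialized cell into a set of codes.

    ``Z`` parses to the empty frozenset (wild type).  Multi-code cells are
    comma-joined, e.g. ``"L,WD"``.
    """
    cell = cell.strip()
    if cell == WILD_TYPE or cell == "":
        return frozenset()
    codes = frozenset(c.strip() for c in cell.split(","))
    bad = codes - set(CODE_ORDER)
    if bad:
        raise MatrixError(f"unknown observation code(s) {sorted(bad)} in cell {cell!r}")
    return codes


def format_code(codes: frozenset[str]) -> str:
    if not codes:
        return WILD_TYPE
    return ",".join(sorted(codes, key=CODE_ORDER.index))


@dataclass(frozen=True)
class EventDef:
    """A candidate driver event (gene-level mutation or GISTIC-style peak)."""

    event_id: str
    label: str
    event_type: str

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise MatrixError(f"unknown event type {self.event_type!r} for {self.label}")
        suffix = TYPE_SUFFIX[self.event_type]
        if not self.label.endswith(suffix):
            raise MatrixError(
                f"label {self.label!r} does not carry the {suffix!r} suffix "
                f"required for event type {self.event_type!r}"
            )

    @property
    def allowed_codes(self) -> frozenset[str]:
        return ALLOWED_CODES[self.event_type]


def event_type_from_label(label: str) -> str:
    """Infer an event type from a label suffix (longest suffix wins)."""
    for etype, suffix in sorted(TYPE_SUFFIX.items(), key=lambda kv: -len(kv[1])):
        if label.endswith(suffix):
            return etype
    raise MatrixError(f"cannot infer event type from label {label!r}")


def _check_labels(labels: list[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise MatrixError(f"duplicate {what} label {lab!r}")
        seen.add(lab)


@dataclass
class CategoricalEventMatrix:
    """Event × sample grid of observation-code sets (``M``)."""

    events: list[EventDef]
    samples: list[str]
    codes: list[list[frozenset[str]]]  # events × samples

    def __post_init__(self):
        _check_labels([e.label for e in self.events], "event")
        _check_labels(self.samples, "sample")
        if len(self.codes) != len(self.events):
            raise MatrixError("code grid row count does not match events")
        for ev, row in zip(self.events, self.codes):
            if len(row) != len(self.samples):
                raise MatrixError(f"row for {ev.label} is not rectangular")
            for sample, cell in zip(self.samples, row):
                if not cell:
                    continue
                if len(cell) > 1 and ev.event_type not in HYBRID_TYPES:
                    raise MatrixError(
                        f"multi-code observation {format_code(cell)} for "
                        f"non-hybrid event {ev.label} in sample {sample}"
                    )
                extra = cell - ev.allowed_codes
                if extra:
                    raise MatrixError(
                        f"code(s) {sorted(extra)} not allowed for event "
                        f"{ev.label} ({ev.event_type}) in sample {sample}"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.events), len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        data = [[format_code(c) for c in row] for row in self.codes]
        return pd.DataFrame(data, index=[e.label for e in self.events], columns=self.samples)


@dataclass
class BinaryEventMatrix:
    """Binary alteration matrix ``D`` (1 where the sample harbors the event)."""

    event_labels: list[str]
    samples: list[str]
    values: np.ndarray  # events × samples, bool

    def __post_init__(self):
        _check_labels(self.event_labels, "event")
        _check_labels(self.samples, "sample")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.event_labels), len(self.samples)):
            raise MatrixError("binary matrix shape does not match labels")
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.isin(uniq, [0, 1]).all():
                raise MatrixError("binary matrix contains values other than 0/1")
            self.values = self.values.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=self.event_labels, columns=self.samples
        )


@dataclass
class PenaltyMatrix:
    """Penalty matrix ``P``: negative log passenger probability per altered cell.

    Natural log throughout; any fixed base rescales the objective uniformly and
    leaves every ranking, assignment and core selection unchanged.
    """

    event_labels: list[str]
    samples: list[str]
    penalties: np.ndarray  # events × samples, float

    def __post_init__(self):
        _check_labels(self.event_labels, "event")
        _check_labels(self.samples, "sample")
        self.penalties = np.asarray(self.penalties, dtype=float)
        if self.penalties.shape != (len(self.event_labels), len(self.samples)):
            raise MatrixError("penalty matrix shape does not match labels")
        if not np.isfinite(self.penalties).all():
            raise MatrixError("penalty matrix contains non-finite entries")
        if (self.penalties < 0).any():
            i, j = np.argwhere(self.penalties < 0)[0]
            raise MatrixError(
                f"negative penalty at event {self.event_labels[i]!r}, "
                f"sample {self.samples[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.penalties.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.penalties, index=self.event_labels, columns=self.samples)


def binarize(m: CategoricalEventMatrix) -> BinaryEventMatrix:
    """Collapse ``M`` to ``D``: a cell is altered iff its code is not wild type."""
    values = np.array([[bool(c) for c in row] for row in m.codes], dtype=bool)
    return BinaryEventMatrix([e.label for e in m.events], list(m.samples), values)


@dataclass
class PairReport:
    """Zero-alignment check between a ``(D, P)`` pair."""

    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.violations


def validate_pair(d: BinaryEventMatrix, p: PenaltyMatrix) -> PairReport:
    """List every cell where the D=0 ⇔ P=0 invariant is broken."""
    if d.event_labels != p.event_labels or d.samples != p.samples:
        raise MatrixError("D and P do not share event/sample ordering")
    report = PairReport()
    zero_on_altered = d.values & (p.penalties == 0)
    nonzero_on_wild = (~d.values) & (p.penalties != 0)
    for i, j in np.argwhere(zero_on_altered):
        report.violations.append((d.event_labels[i], d.samples[j], "D=1 but P=0"))
    for i, j in np.argwhere(nonzero_on_wild):
        report.violations.append((d.event_labels[i], d.samples[j], "D=0 but P>0"))
    return report


# ---------------------------------------------------------------------------
# TSV serialization (events × samples; header row = sample ids)
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixError(f"duplicate event labels {dups} in {path}")
    return df


def read_matrix(path, kind: str):
    """Read a matrix TSV.  ``kind`` is ``binary``, ``penalty`` or ``categorical``."""
    df = _read_tsv(path)
    labels = [str(x) for x in df.index]
    samples = [str(c) for c in df.columns]
    if kind == "binary":
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise MatrixError(f"non-numeric cell in binary matrix {path}: {exc}") from exc
        return BinaryEventMatrix(labels, samples, values)
    if kind == "penalty":
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise MatrixError(f"non-numeric cell in penalty matrix {path}: {exc}") from exc
        return PenaltyMatrix(labels, samples, values)
    if kind == "categorical":
        events = [EventDef(lab, lab, event_type_from_label(lab)) for lab in labels]
        codes = [[parse_code(df.iat[i, j]) for j in range(len(samples))] for i in range(len(labels))]
        return CategoricalEventMatrix(events, samples, codes)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix, path) -> None:
    """Write any of the three matrix types as TSV (round-trips with read_matrix)."""
    df = matrix.to_frame()
    if isinstance(matrix, PenaltyMatrix):
        df.to_csv(path, sep="\t", float_format="%.10g")
    else:
        df.to_csv(path, sep="\t")
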