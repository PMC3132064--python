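"""Cohort design and expression-matrix containers with tab-delimited IO.

The study design distinguishes three roles: the proband (``P``, the twin
affected with a systemic autoimmune disease), the unaffected co-twin (``U``)
and unrelated matched controls (``C``).  A *matched set* groups one twin pair
with its controls (two per pair in the motivating design, matched on age, sex
and ethnicity); it is the stratification unit for the versus-control
contrasts.  Expression values are base-2 logarithms of two-color ratios
(subject over a universal reference RNA), one value per probe and sample.

File dialect: UTF-8, tab-separated, ``NA`` as the missing token, ``.`` as the
decimal mark.  ``write_matrix(read_matrix(f))`` reproduces ``f`` byte for byte
when ``f`` is in the canonical fixed-precision format.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import FormatError, ValidationError

ROLES = ("P", "U", "C")
SUBTYPES = ("SLE", "RA", "IIM", "NONE")
NA_TOKEN = "NA"

DESIGN_COLUMNS = (
    "subject_id",
    "role",
    "pair_id",
    "set_id",
    "subtype",
    "batch_id",
    "age",
    "sex",
    "ethnicity",
)


@dataclass(frozen=True)
class SampleRecord:
    """One subject in the cohort.

    ``pair_id`` is empty for controls and names the twin pair for roles
    ``P``/``U``; ``set_id`` names the matched set and is never empty.
    """

    subject_id: str
    role: str
    pair_id: str
    set_id: str
    subtype: str
    batch_id: str
    age: float
    sex: str
    ethnicity: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"subject {self.subject_id!r}: unknown role {self.role!r}"
            )
        if self.subtype not in SUBTYPES:
            raise ValidationError(
                f"subject {self.subject_id!r}: unknown subtype {self.subtype!r}"
            )
        if self.sex not in ("F", "M"):
            raise ValidationError(
                f"subject {self.subject_id!r}: unknown sex {self.sex!r}"
            )


@dataclass
class CohortDesign:
    """Ordered collection of :class:`SampleRecord` with design invariants.

    Invariants enforced at construction:

    * subject ids are unique;
    * every ``set_id`` is nonempty;
    * controls carry no pair id and subtype ``NONE``; twins carry a pair id;
    * every pair id occurs exactly twice, once as ``P`` and once as ``U``;
    * every matched set holds exactly one complete twin pair and at least
      one control.
    """

    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if not self.samples:
            raise ValidationError("no samples")
        bad: list[str] = []
        seen: set[str] = set()
        for s in self.samples:
            if s.subject_id in seen:
                raise ValidationError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)
            if not s.set_id:
                bad.append(s.subject_id)
            if s.role == "C" and (s.pair_id or s.subtype != "NONE"):
                bad.append(s.subject_id)
            if s.role in ("P", "U") and not s.pair_id:
                bad.append(s.subject_id)
        if bad:
            raise ValidationError(
                "invalid role/pair/set fields for subjects: " + ", ".join(sorted(set(bad)))
            )
        # each pair id: exactly one P and one U
        roles_by_pair: dict[str, list[str]] = {}
        for s in self.samples:
            if s.pair_id:
                roles_by_pair.setdefault(s.pair_id, []).append(s.role)
        bad_pairs = [p for p, r in roles_by_pair.items() if sorted(r) != ["P", "U"]]
        if bad_pairs:
            raise ValidationError(
                "twin pairs without exactly one P and one U: " + ", ".join(sorted(bad_pairs))
            )
        # each set: one complete pair plus >=1 control
        by_set: dict[str, list[SampleRecord]] = {}
        for s in self.samples:
            by_set.setdefault(s.set_id, []).append(s)
        bad_sets = []
        for set_id, members in by_set.items():
            pairs = {m.pair_id for m in members if m.pair_id}
            n_ctrl = sum(m.role == "C" for m in members)
            n_p = sum(m.role == "P" for m in members)
            n_u = sum(m.role == "U" for m in members)
            if len(pairs) != 1 or n_p != 1 or n_u != 1 or n_ctrl < 1:
                bad_sets.append(set_id)
        if bad_sets:
            raise ValidationError(
                "matched sets without one complete twin pair plus controls: "
                + ", ".join(sorted(bad_sets))
            )

    # -- accessors --------------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.samples]

    def roles(self) -> np.ndarray:
        return np.array([s.role for s in self.samples])

    def batches(self) -> np.ndarray:
        return np.array([s.batch_id for s in self.samples])

    def index_of(self) -> dict[str, int]:
        return {s.subject_id: i for i, s in enumerate(self.samples)}

    def pairs(self) -> dict[str, dict[str, str]]:
        """Map pair_id -> {'P': subject_id, 'U': subject_id}."""
        out: dict[str, dict[str, str]] = {}
        for s in self.samples:
            if s.pair_id:
                out.setdefault(s.pair_id, {})[s.role] = s.subject_id
        return out

    def sets(self) -> dict[str, dict[str, object]]:
        """Map set_id -> {'P': id, 'U': id, 'C': [ids...], 'subtype': str}."""
        out: dict[str, dict[str, object]] = {}
        for s in self.samples:
            d = out.setdefault(s.set_id, {"C": []})
            if s.role == "C":
                d["C"].append(s.subject_id)  # type: ignore[union-attr]
            else:
                d[s.role] = s.subject_id
                d["subtype"] = s.subtype
        return out

    def subtype_of_pair(self) -> dict[str, str]:
        return {s.pair_id: s.subtype for s in self.samples if s.role == "P"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.samples], columns=DESIGN_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortDesign":
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError("design table missing column(s): " + ", ".join(missing))
        extra = [c for c in df.columns if c not in DESIGN_COLUMNS]
        if extra:
            warnings.warn(f"ignoring unknown design columns: {', '.join(extra)}")
        if len(df) == 0:
            raise ValidationError("no samples")
        records = [
            SampleRecord(
                subject_id=str(r.subject_id),
                role=str(r.role),
                pair_id="" if pd.isna(r.pair_id) else str(r.pair_id),
                set_id=str(r.set_id),
                subtype=str(r.subtype),
                batch_id=str(r.batch_id),
                age=float(r.age),
                sex=str(r.sex),
                ethnicity=str(r.ethnicity),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(records)


@dataclass
class ProbeMatrix:
    """Probe x sample grid of base-2 log expression ratios.

    ``values`` has shape (n_probes, n_samples); missing cells are ``NaN``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "ProbeMatrix":
        return ProbeMatrix(list(self.probe_ids), list(self.sample_ids), self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def column_indices(self, subject_ids: Iterable[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([idx[s] for s in subject_ids], dtype=int)


# ---------------------------------------------------------------------------
# readers / writers


def read_design(path) -> CohortDesign:
    """Read a tab-delimited sample design table into a validated design."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "age" in df.columns:
        df = df.assign(age=pd.to_numeric(df["age"], errors="raise"))
    return CohortDesign.from_frame(df)


def write_design(design: CohortDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix(path) -> ProbeMatrix:
    """Read a probe x sample matrix TSV (first column: probe id; NA = missing)."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise FormatError("empty matrix file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError("matrix header names no samples")
    n_cols = len(header)
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise FormatError(
                f"line {lineno}: expected {n_cols} columns, found {len(cells)}"
            )
        pid = cells[0]
        if pid in seen:
            raise FormatError(f"duplicate probe id {pid!r}")
        seen.add(pid)
        probe_ids.append(pid)
        try:
            rows.append([np.nan if c == NA_TOKEN else float(c) for c in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    if not probe_ids:
        raise FormatError("matrix file has no probe rows")
    return ProbeMatrix(probe_ids, sample_ids, np.array(rows, dtype=float))


def write_matrix(matrix: ProbeMatrix, path, decimals: int = 6) -> None:
    """Write a matrix TSV at fixed decimal precision (missing -> ``NA``)."""

    def _render(fh) -> None:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.probe_ids, matrix.values):
            cells = [
                NA_TOKEN if np.isnan(v) else f"{v:.{decimals}f}" for v in row
            ]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")

    if hasattr(path, "write"):
        _render(path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            _render(fh)


def matrix_to_string(matrix: ProbeMatrix, decimals: int = 6) -> str:
    buf = _io.StringIO()
    write_matrix(matrix, buf, decimals=decimals)
    return buf.getvalue()


def align(matrix: ProbeMatrix, design: CohortDesign) -> ProbeMatrix:
    """Reorder matrix columns to the design's sample order.

    The sample-id sets must match exactly; the symmetric difference is
    reported otherwise.
    """
    m_set, d_set = set(matrix.sample_ids), set(design.subject_ids)
    if m_set != d_set:
        diff = sorted(m_set.symmetric_difference(d_set))
        raise ValidationError(
            "matrix/design sample mismatch: " + ", ".join(diff)
        )
    order = matrix.column_indices(design.subject_ids)
    return ProbeMatrix(
        list(matrix.probe_ids), list(design.subject_ids), matrix.values[:, order]
    )


def check_matching(design: CohortDesign, max_age_gap: float = 6.0) -> list[str]:
    """Soft check of control matching quality (age gap, sex, ethnicity).

    Returns warning strings (also emitted via :mod:`warnings`); imperfect
    matching never blocks the pipeline.
    """
    msgs: list[str] = []
    by_id = {s.subject_id: s for s in design.samples}
    for set_id, members in design.sets().items():
        proband = by_id[members["P"]]  # type: ignore[index]
        for cid in members["C"]:  # type: ignore[union-attr]
            ctrl = by_id[cid]
            if abs(ctrl.age - proband.age) > max_age_gap:
                msgs.append(
                    f"set {set_id}: control {cid} age gap "
                    f"{abs(ctrl.age - proband.age):.1f} > {max_age_gap}"
                )
            if ctrl.sex != proband.sex:
                msgs.append(f"set {set_id}: control {cid} sex mismatch")
            if ctrl.ethnicity != proband.ethnicity:
                msgs.append(f"set {set_id}: control {cid} ethnicity mismatch")
    for m in msgs:
        warnings.warn(m)
    return msgs
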