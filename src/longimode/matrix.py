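"""Subjects x variables matrices with explicit missingness and provenance.

The missingness mask is authoritative: a masked cell carries no
information and is never read by any stage.  Provenance tags record the
conditioning state of a matrix and may only advance along
``raw -> normalized -> deconfounded -> imputed``, which lets downstream
stages reject inputs that skipped a conditioning step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROVENANCE_ORDER = ("raw", "normalized", "deconfounded", "imputed")
MISSING_TOKEN = "NA"


class ProvenanceError(ValueError):
    """Raised when a stage receives a matrix in the wrong conditioning state."""


@dataclass
class SubjectMatrix:
    subjects: list
    variables: list
    values: np.ndarray
    mask: np.ndarray = None  # True where missing
    provenance: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.subjects), len(self.variables)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variables)} variables"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")
        if self.provenance not in PROVENANCE_ORDER:
            raise ValueError(f"unknown provenance tag {self.provenance!r}")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject id")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable id")

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "SubjectMatrix":
        return SubjectMatrix(list(self.subjects), list(self.variables),
                             self.values.copy(), self.mask.copy(), self.provenance)

    def col_index(self, var_id) -> int:
        try:
            return self.variables.index(var_id)
        except ValueError:
            raise KeyError(f"unknown variable id {var_id!r}") from None

    def column(self, var_id):
        """Observed values and mask of one variable."""
        j = self.col_index(var_id)
        return self.values[:, j], self.mask[:, j]

    def n_observed(self):
        return (~self.mask).sum(axis=0)

    def select_variables(self, ids) -> "SubjectMatrix":
        idx = [self.col_index(i) for i in ids]
        return SubjectMatrix(list(self.subjects), list(ids),
                             self.values[:, idx], self.mask[:, idx], self.provenance)

    def select_subjects(self, subject_ids) -> "SubjectMatrix":
        pos = {s: i for i, s in enumerate(self.subjects)}
        idx = [pos[s] for s in subject_ids]
        return SubjectMatrix(list(subject_ids), list(self.variables),
                             self.values[idx], self.mask[idx], self.provenance)

    def advance_provenance(self, tag) -> None:
        """Move the provenance tag forward; moving backwards is an error."""
        old = PROVENANCE_ORDER.index(self.provenance)
        new = PROVENANCE_ORDER.index(tag)
        if new < old:
            raise ProvenanceError(
                f"provenance may not move backwards ({self.provenance} -> {tag})"
            )
        self.provenance = tag

    def require_provenance(self, *tags) -> None:
        if self.provenance not in tags:
            raise ProvenanceError(
                f"expected provenance in {tags}, got {self.provenance!r}"
            )

    # -- pandas bridge ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.mask] = np.nan
        return pd.DataFrame(vals, index=pd.Index(self.subjects, name="subject"),
                            columns=self.variables)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance="raw") -> "SubjectMatrix":
        vals = df.to_numpy(dtype=float)
        mask = np.isnan(vals)
        out = cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                  np.nan_to_num(vals), mask, provenance)
        return out


@dataclass
class ConfoundSet:
    """The five nuisance covariates regressed out of every variable."""

    NAMES = ("motion_abs", "motion_rel", "head_size", "age_diff", "age_avg")

    subjects: list
    values: np.ndarray
    names: tuple = NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.names) != self.NAMES:
            raise ValueError(f"confound names fixed to {self.NAMES}")
        if self.values.shape != (len(self.subjects), 5):
            raise ValueError("confound matrix must be subjects x 5")
        if np.isnan(self.values).any():
            raise ValueError("confounds may not contain missing values")

    def select_subjects(self, subject_ids) -> "ConfoundSet":
        pos = {s: i for i, s in enumerate(self.subjects)}
        return ConfoundSet(list(subject_ids),
                           self.values[[pos[s] for s in subject_ids]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subjects, name="subject"),
                            columns=list(self.names))


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_dataset(m: SubjectMatrix, path) -> None:
    """Write a tab-separated file with header; masked cells as ``NA``.

    Values are written with ``repr`` precision so that a read-back is
    bit-exact.
    """
    with open(path, "w") as fh:
        fh.write("subject\t" + "\t".join(m.variables) + "\n")
        for i, s in enumerate(m.subjects):
            cells = [
                MISSING_TOKEN if m.mask[i, j] else repr(float(m.values[i, j]))
                for j in range(len(m.variables))
            ]
            fh.write(str(s) + "\t" + "\t".join(cells) + "\n")


def load_dataset(path, registry=None, provenance="raw") -> SubjectMatrix:
    """Read a tab-separated subjects x variables file.

    The header row carries variable ids; the ``NA`` token marks missing
    cells.  When a registry is given, every column must be a known analysis
    variable or source measurement, and columns are reordered to registry
    order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate subject id {dup!r}")
    vals = np.empty(df.shape, dtype=float)
    mask = np.zeros(df.shape, dtype=bool)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col].to_numpy()):
            if cell == MISSING_TOKEN:
                mask[i, j] = True
                vals[i, j] = 0.0
            else:
                try:
                    vals[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} in column {col!r} "
                        f"(missing token is {MISSING_TOKEN!r})"
                    ) from None
    m = SubjectMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                      vals, mask, provenance)
    if registry is not None:
        known = set(v.id for v in registry.variables)
        known |= {v.source for v in registry.variables}
        unknown = [c for c in m.variables if c not in known]
        if unknown:
            raise ValueError(f"variable ids not in registry: {unknown[:5]}")
        order = [v for v in _registry_order(registry) if v in set(m.variables)]
        if order != m.variables:
            m = m.select_variables(order)
    return m


def _registry_order(registry):
    seen, out = set(), []
    for v in registry.variables:
        for vid in (v.id, v.source):
            if vid not in seen:
                seen.add(vid)
                out.append(vid)
    return out


def load_confounds(path) -> ConfoundSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df[list(ConfoundSet.NAMES)]
    return ConfoundSet(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_confounds(c: ConfoundSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("subject\t" + "\t".join(c.names) + "\n")
        for i, s in enumerate(c.subjects):
            fh.write(str(s) + "\t" + "\t".join(repr(float(x)) for x in c.values[i]) + "\n")
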