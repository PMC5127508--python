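"""Readers, writers, z-scoring and aberrance calling.

File dialects
-------------
Expression: tab-delimited, first column ``Hugo_Symbol`` (gene symbols),
remaining columns sample ids — the cBioPortal tab-delimited export shape.
Clinical: tab-delimited, one row per sample, required columns
``sample_id``, ``os_months``, ``event``; optional ``grade``,
``idh1_mutated``, ``dfs_months``. Panels: one gene symbol per line,
``#`` comments allowed.

Aberrance semantics: a (gene, sample) cell is *aberrant* when the absolute
value of the gene's z-score — computed relative to the average expression of
that gene across all samples — is strictly greater than the threshold
(default 2). Missing expression is never aberrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenePanel",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_panel_file",
    "load_panel",
    "available_panels",
    "compute_zscores",
    "call_aberrant",
    "panel_aberrance_label",
]

EXPRESSION_INDEX = "Hugo_Symbol"

# Registry of panels shipped as package data. The 61-gene and 16-gene files
# are constructed stand-ins for published lists (see the files' headers);
# the 8-gene signature is complete.
_PANEL_FILES = {
    "iron61": "iron61_synthetic.txt",
    "irgs16": "irgs16_synthetic.txt",
    "selected8": "selected8.txt",
}


@dataclass(frozen=True)
class GenePanel:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ValueError(f"panel {self.name!r} has duplicate genes: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    Missing cells stay missing (NaN), never silently zero. Duplicate gene
    symbols or sample ids, and non-numeric cells, are errors naming the
    offending coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dupes = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicate gene symbols in {path}: {dupes}")
    if raw.columns.duplicated().any():
        dupes = sorted(raw.columns[raw.columns.duplicated()].unique())
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    expr = raw.apply(pd.to_numeric, errors="coerce")
    # Cells that were non-empty text but failed numeric conversion.
    nonblank = raw.apply(lambda col: col.astype(str).str.strip() != "")
    bad = expr.isna() & raw.notna() & nonblank
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        coords = [
            f"(gene={expr.index[r]}, sample={expr.columns[c]}, value={raw.iat[r, c]!r})"
            for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(f"non-numeric expression cells in {path}: {', '.join(coords)}")
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Write the expression TSV dialect :func:`read_expression` reads."""
    out = expr.copy()
    out.index.name = EXPRESSION_INDEX
    out.to_csv(path, sep="\t", float_format="%.10g")


_REQUIRED_CLINICAL = ("sample_id", "os_months", "event")
_TRUTHY = {"1", "true", "yes", "deceased", "dead", "event"}
_FALSY = {"0", "false", "no", "living", "alive", "censored"}


def _parse_bool(value, column: str):
    if pd.isna(value):
        return pd.NA
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"cannot parse {column} value {value!r} as boolean")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical TSV.

    Returns a DataFrame indexed by ``sample_id`` with columns
    ``os_months`` (float), ``event`` (bool; True = deceased, False =
    censored/alive at end of study) and, when present, ``grade`` (II/III/IV
    or missing), ``idh1_mutated`` (nullable bool), ``dfs_months`` (float).
    Unknown grade labels become missing with a warning; negative survival
    months are an error.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_CLINICAL if c not in raw.columns]
    if missing:
        raise ValueError(f"clinical table {path} lacks required columns: {missing}")
    if raw["sample_id"].duplicated().any():
        dupes = sorted(raw["sample_id"][raw["sample_id"].duplicated()].unique())
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")

    table = pd.DataFrame(index=pd.Index(raw["sample_id"].astype(str), name="sample_id"))
    os_months = pd.to_numeric(raw["os_months"], errors="raise").astype(float)
    if (os_months < 0).any():
        bad = raw["sample_id"][os_months.to_numpy() < 0].tolist()
        raise ValueError(f"negative os_months for samples {bad}")
    table["os_months"] = os_months.to_numpy()
    table["event"] = [_parse_bool(v, "event") for v in raw["event"]]
    table["event"] = table["event"].astype(bool)

    if "grade" in raw.columns:
        grades = []
        for v in raw["grade"]:
            if pd.isna(v) or str(v).strip() == "":
                grades.append(pd.NA)
                continue
            text = str(v).strip().upper().replace("GRADE", "").strip()
            mapped = {"2": "II", "3": "III", "4": "IV"}.get(text, text)
            if mapped not in ("II", "III", "IV"):
                warnings.warn(f"unknown grade value {v!r} treated as missing")
                mapped = pd.NA
            grades.append(mapped)
        table["grade"] = grades
    else:
        table["grade"] = pd.NA
    if "idh1_mutated" in raw.columns:
        table["idh1_mutated"] = pd.array(
            [_parse_bool(v, "idh1_mutated") for v in raw["idh1_mutated"]],
            dtype="boolean",
        )
    if "dfs_months" in raw.columns:
        table["dfs_months"] = pd.to_numeric(raw["dfs_months"], errors="coerce").to_numpy()
    return table


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out.index.name = "sample_id"
    if "event" in out.columns:
        out["event"] = out["event"].astype(int)
    if "idh1_mutated" in out.columns:
        out["idh1_mutated"] = out["idh1_mutated"].astype("Int64")
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_panel_file(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a one-symbol-per-line panel file (``#`` comments ignored)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return GenePanel(name=name or Path(path).stem, genes=tuple(genes))


def available_panels() -> tuple[str, ...]:
    return tuple(_PANEL_FILES)


def load_panel(name: str) -> GenePanel:
    """Load a bundled panel by registry name (``iron61``/``irgs16``/``selected8``)."""
    if name not in _PANEL_FILES:
        raise KeyError(f"unknown panel {name!r}; available: {sorted(_PANEL_FILES)}")
    ref = resources.files("ironsig.panels") / _PANEL_FILES[name]
    with resources.as_file(ref) as path:
        return read_panel_file(path, name=name)


def compute_zscores(expr: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z-scores across all samples.

    ``(x - mean) / sd`` per gene row, with the sample SD (``ddof=1``) by
    default. Zero-variance genes yield all-zero rows with a warning;
    missing cells are excluded from the mean/SD and stay missing.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    values = expr.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        sd = np.nanstd(values, axis=1, ddof=ddof, keepdims=True)
    flat = (np.nan_to_num(sd) == 0) & ~np.isnan(values).all(axis=1, keepdims=True)
    if flat.any():
        genes = [expr.index[i] for i in np.nonzero(flat.ravel())[0]]
        warnings.warn(f"zero-variance genes z-scored to 0: {genes}")
    safe_sd = np.where(np.nan_to_num(sd) == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z = np.where(np.broadcast_to(flat, z.shape), 0.0, z)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def call_aberrant(z: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Boolean genes x samples matrix of ``|z| > threshold`` calls.

    The inequality is strict; missing z-scores are never aberrant.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    values = z.to_numpy(dtype=float)
    calls = np.abs(values) > threshold
    calls &= ~np.isnan(values)
    return pd.DataFrame(calls, index=z.index, columns=z.columns)


def panel_aberrance_label(aberrant: pd.DataFrame, panel: GenePanel) -> pd.Series:
    """Per-sample flag: at least one panel gene aberrant in that sample."""
    missing = [g for g in panel.genes if g not in aberrant.index]
    if missing:
        raise KeyError(f"panel {panel.name!r} genes absent from matrix: {missing}")
    return aberrant.loc[list(panel.genes)].any(axis=0)
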