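"""Putative peptide annotation of spectral components by mass matching.

Component m/z values (MALDI [M+H]+ species) are matched against a list of
measured peptide masses from LC-MS/MS identifications of tissue lysates,
within a relative mass tolerance (default +/-0.05%).  The mass convention
of the peptide list (neutral vs protonated) is the data file's declaration;
the matcher compares the numbers as given.  Annotation is not unique:
several peptides may fall inside one component's tolerance window, and all
matches are kept.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError
from .gmm import ComponentModel

PEPTIDE_COLUMNS = ("measured_mass", "sequence", "protein", "source")


def read_peptide_list(path: str | Path) -> pd.DataFrame:
    """Read a peptide CSV with columns measured_mass, sequence, protein,
    source (source = lysate class the identification came from)."""
    peptides = pd.read_csv(path)
    missing = [c for c in PEPTIDE_COLUMNS if c not in peptides.columns]
    if missing:
        raise DataError(f"peptide list {path} missing columns: {missing}")
    validate_peptides(peptides)
    return peptides


def validate_peptides(peptides: pd.DataFrame) -> None:
    if len(peptides) == 0:
        raise DataError("peptide list is empty")
    if (peptides["measured_mass"] <= 0).any():
        raise DataError("peptide masses must be positive")
    if peptides["sequence"].astype(str).str.len().eq(0).any():
        raise DataError("peptide sequences must be non-empty")


def match_components(model: ComponentModel | np.ndarray,
                     peptides: pd.DataFrame,
                     tol: float = 0.0005) -> pd.DataFrame:
    """Match component m/z values to peptide masses within ``tol`` relative.

    A component at m/z ``m`` matches every peptide with
    ``|measured_mass - m| <= tol * m``.  Returns one row per match, sorted
    per component by |relative error|; unmatched components appear once
    with NaN peptide fields.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    validate_peptides(peptides)
    mzs = model.mz_values if isinstance(model, ComponentModel) \
        else np.asarray(model, float)
    masses = peptides["measured_mass"].to_numpy(float)
    rows = []
    for mz in mzs:
        err = (masses - mz) / mz
        hits = np.flatnonzero(np.abs(err) <= tol)
        if hits.size == 0:
            rows.append({"component_mz": float(mz), "measured_mass": np.nan,
                         "sequence": None, "protein": None, "source": None,
                         "relative_error": np.nan})
            continue
        for h in hits[np.argsort(np.abs(err[hits]))]:
            rec = peptides.iloc[h]
            rows.append({"component_mz": float(mz),
                         "measured_mass": float(rec["measured_mass"]),
                         "sequence": rec["sequence"],
                         "protein": rec["protein"],
                         "source": rec["source"],
                         "relative_error": float(err[h])})
    return pd.DataFrame(rows)
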