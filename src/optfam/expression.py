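"""Digital expression: tpm normalization, response calls, diversification.

Tag counts from MPSS-style libraries are normalized to tags per million
(tpm).  A gene responds to a treatment when its treatment/control fold
change is at least the threshold (default two-fold, boundary inclusive) in
either direction; pairs of duplicated genes are scored for expression
diversification per condition class ('+' when the two members' call
vectors differ in at least one contrast of that class, '−' otherwise).

Library metadata drives everything: each library carries a tissue, a
condition class and, for treatment libraries, the name of its control
library.  The default condition classes mirror a developmental/stress
survey: Tissues, Salt, Drought, Cold, X. oryzae, M. grisea.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_CLASSES = ("Tissues", "Salt", "Drought", "Cold", "X. oryzae", "M. grisea")
DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_PSEUDO_TPM = 1.0
DEFAULT_MIN_TPM = 1.0

#: Library metadata columns: library id (index), tissue, condition class,
#: and the id of the matching control library ('' for controls).
META_COLUMNS = ("tissue", "class", "control_library")


def normalize_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Tags per million: count / library total × 10⁶, per library column."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative tag counts")
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero tag total in library {zero.index[0]!r}")
    return counts / totals * 1e6


def call_presence(
    tpm: pd.DataFrame | pd.Series, min_tpm: float = DEFAULT_MIN_TPM
):
    """Present iff tpm ≥ min_tpm."""
    if min_tpm < 0:
        raise ValueError("min_tpm must be ≥ 0")
    return tpm >= min_tpm


@dataclass(frozen=True)
class ResponseCall:
    call: str  # up | down | none | not_assessable
    fold: float


def call_response(
    control_tpm: float,
    treatment_tpm: float,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudo: float = DEFAULT_PSEUDO_TPM,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> ResponseCall:
    """Two-fold-rule response call for one gene in one contrast.

    The boundary is inclusive ("at least" a fold_threshold change in
    either direction).  A pseudo-count (in tpm) stabilizes folds when the
    control is near zero; with both values below min_tpm the gene is not
    assessable in that contrast.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if max(control_tpm, treatment_tpm) < min_tpm:
        return ResponseCall("not_assessable", float("nan"))
    fold = (treatment_tpm + pseudo) / (control_tpm + pseudo)
    if fold >= fold_threshold:
        return ResponseCall("up", fold)
    if fold <= 1.0 / fold_threshold:
        return ResponseCall("down", fold)
    return ResponseCall("none", fold)


def response_profiles(
    tpm: pd.DataFrame,
    meta: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudo: float = DEFAULT_PSEUDO_TPM,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> pd.DataFrame:
    """Per-gene response calls for every treatment library (contrast).

    ``meta`` is indexed by library with columns ``tissue``, ``class`` and
    ``control_library``; rows with a non-empty control define contrasts.
    Returns a long table: gene, contrast, class, call, fold.
    """
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"library metadata missing columns {sorted(missing)}")
    unknown = set(meta.index) - set(tpm.columns)
    if unknown:
        raise ValueError(f"metadata for absent libraries {sorted(unknown)}")
    rows = []
    for lib, info in meta.iterrows():
        control = info["control_library"]
        if not isinstance(control, str) or not control:
            continue
        if control not in tpm.columns:
            raise ValueError(f"control library {control!r} for {lib!r} absent")
        for gene in tpm.index:
            rc = call_response(
                tpm.at[gene, control], tpm.at[gene, lib],
                fold_threshold, pseudo, min_tpm,
            )
            rows.append({
                "gene": gene, "contrast": lib, "class": info["class"],
                "call": rc.call, "fold": rc.fold,
            })
    return pd.DataFrame(rows, columns=["gene", "contrast", "class", "call", "fold"])


def diversification_matrix(
    profiles: pd.DataFrame,
    presence: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    classes: Sequence[str] = DEFAULT_CLASSES,
    tissue_class: str = "Tissues",
) -> pd.DataFrame:
    """Expression-diversification table for duplicated pairs.

    One row per pair with one column per condition class, '+' when the two
    members differ in at least one contrast of that class and '−'
    otherwise.  The tissue class compares presence/absence vectors across
    the libraries of that class; the remaining classes compare up/down/none
    response calls.  Symmetric in pair order; a contrast where the members
    agree can never turn a '+' into a '−'.
    """
    tissue_libs = [
        lib for lib, info in meta.iterrows() if info["class"] == tissue_class
    ]
    by_gene = {
        g: sub.set_index("contrast") for g, sub in profiles.groupby("gene")
    }
    rows = []
    for a, b in pairs:
        for gene in (a, b):
            if gene not in presence.index:
                raise KeyError(f"pair member {gene} not profiled")
        row: dict[str, str] = {"pair": f"{a}/{b}"}
        for cls in classes:
            if cls == tissue_class:
                va = presence.loc[a, tissue_libs]
                vb = presence.loc[b, tissue_libs]
                differs = bool((va != vb).any())
            else:
                pa = by_gene.get(a)
                pb = by_gene.get(b)
                contrasts = (
                    sorted(set(pa.index[pa["class"] == cls]))
                    if pa is not None else []
                )
                differs = False
                for c in contrasts:
                    ca = pa.at[c, "call"] if pa is not None else "none"
                    cb = pb.at[c, "call"] if pb is not None else "none"
                    if ca != cb:
                        differs = True
                        break
            row[cls] = "+" if differs else "−"
        rows.append(row)
    return pd.DataFrame(rows, columns=["pair", *classes])
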