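"""Family identification by signature motif and protein parameters.

Membership in the oligopeptide transporter (OPT) family is screened by the
conserved ``SPYxEVRxxVxxxDDP`` signature (``x`` = any residue) together with
the gross protein parameters transporter surveys tabulate: length, average
molecular weight, isoelectric point and predicted transmembrane-segment
count.  OPT proteins are polytopic membrane proteins, typically 12–16
transmembrane helices and 50–90 kDa.

Transmembrane segments are flagged with a Kyte–Doolittle hydropathy window
(window 19, window-mean threshold 1.6, overlapping qualifying windows merged)
— a deterministic approximation of a dedicated HMM-based topology predictor,
adequate for distinguishing multi-spanning membrane proteins from soluble
ones but not a per-helix topology prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

log = logging.getLogger(__name__)

WATER_MASS = 18.0153  # average mass of H2O, Da

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue masses (Da): free amino-acid masses minus one water.
RESIDUE_MASSES: dict[str, float] = {
    aa: protein_weights[aa] - WATER_MASS for aa in AMINO_ACIDS
}

#: pKa values in the style of the Bjellqvist/ExPASy set.  Positive groups
#: contribute +1 when protonated, negative groups −1 when deprotonated.
DEFAULT_PKA: dict[str, float] = {
    "Nterm": 7.5,
    "Cterm": 3.55,
    "K": 10.0,
    "R": 12.0,
    "H": 5.98,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
}
_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")

TM_WINDOW = 19
TM_THRESHOLD = 1.6


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its locus identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class ProteinParams:
    length: int
    mw: float  # kDa
    pi: float  # pH units
    tm_count: int


@dataclass(frozen=True)
class MotifHit:
    start: int  # 1-based
    matched: str


@dataclass
class FamilyMember:
    record: ProteinRecord
    params: ProteinParams
    hits: list[MotifHit] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.record.id


def _check_pattern(pattern: str) -> None:
    if not pattern:
        raise ValueError("empty motif pattern")
    bad = [c for c in pattern if c != "x" and c not in AMINO_ACIDS]
    if bad:
        raise ValueError(
            f"invalid pattern characters {bad}; use uppercase amino acids "
            "and lowercase 'x' wildcards"
        )


def scan_motif(protein: ProteinRecord, pattern: str) -> list[MotifHit]:
    """Find every (possibly overlapping) occurrence of a motif.

    ``x`` matches any single residue; all other positions must match
    exactly.  Hits are reported 1-based in order of start position.
    """
    _check_pattern(pattern)
    seq = protein.sequence.upper()
    m = len(pattern)
    hits: list[MotifHit] = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if all(p == "x" or p == s for p, s in zip(pattern, window)):
            hits.append(MotifHit(start=i + 1, matched=window))
    return hits


def _net_charge(
    counts: Mapping[str, int], ph: float, pka: Mapping[str, float]
) -> float:
    charge = 0.0
    for group in _POSITIVE:
        n = 1 if group == "Nterm" else counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[group]))
    for group in _NEGATIVE:
        n = 1 if group == "Cterm" else counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[group] - ph))
    return charge


def isoelectric_point(
    sequence: str, pka: Mapping[str, float] | None = None, tol: float = 1e-6
) -> float:
    """pH at which the Henderson–Hasselbalch net charge is zero.

    The charge is strictly decreasing in pH, so plain bisection over
    pH 0–14 converges; X residues carry no charge.
    """
    pka = dict(DEFAULT_PKA if pka is None else pka)
    counts = {aa: sequence.count(aa) for aa in "KRHDECY"}
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _net_charge(counts, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def molecular_weight_kda(
    sequence: str, masses: Mapping[str, float] | None = None
) -> float:
    """Average molecular weight in kDa: residue masses plus one water."""
    masses = dict(RESIDUE_MASSES if masses is None else masses)
    x_mass = masses.get("X", sum(RESIDUE_MASSES.values()) / len(RESIDUE_MASSES))
    total = WATER_MASS
    for aa in sequence:
        total += x_mass if aa == "X" else masses[aa]
    return total / 1000.0


def count_tm_segments(
    sequence: str,
    scale: Mapping[str, float] | None = None,
    window: int = TM_WINDOW,
    threshold: float = TM_THRESHOLD,
) -> int:
    """Count maximal runs of hydropathy windows whose mean exceeds threshold.

    Overlapping qualifying windows merge into one segment, so the count is
    a lower bound on the number of membrane-spanning helices for tightly
    packed transporters; sequences shorter than the window score 0.
    """
    scale = dict(KYTE_DOOLITTLE if scale is None else scale)
    values = [scale.get(aa, 0.0) for aa in sequence]  # X → 0 (neutral)
    n = len(values)
    if n < window:
        return 0
    running = sum(values[:window])
    qualifying = [running / window > threshold]
    for i in range(1, n - window + 1):
        running += values[i + window - 1] - values[i - 1]
        qualifying.append(running / window > threshold)
    segments = 0
    prev = False
    for q in qualifying:
        if q and not prev:
            segments += 1
        prev = q
    return segments


def protein_params(
    protein: ProteinRecord,
    pka_table: Mapping[str, float] | None = None,
    hydropathy_scale: Mapping[str, float] | None = None,
    masses: Mapping[str, float] | None = None,
) -> ProteinParams:
    """Compute length, MW (kDa), pI and transmembrane-segment count."""
    seq = protein.sequence.upper()
    if "X" in seq:
        log.warning(
            "%s: %d X residues excluded from charge, averaged for mass",
            protein.id, seq.count("X"),
        )
    return ProteinParams(
        length=len(seq),
        mw=molecular_weight_kda(seq, masses),
        pi=isoelectric_point(seq, pka_table),
        tm_count=count_tm_segments(seq, hydropathy_scale),
    )


def filter_family(
    candidates: Sequence[ProteinRecord],
    pattern: str,
    params_window: Mapping[str, tuple[float | None, float | None]] | None = None,
    **params_kwargs,
) -> list[FamilyMember]:
    """Retain candidates with ≥1 motif hit and parameters inside the window.

    ``params_window`` maps a parameter name (``length``, ``mw``,
    ``tm_count``) to an inclusive ``(min, max)`` range; ``None`` ends are
    open.  Input order is preserved; applying the filter to its own output
    is a no-op.
    """
    params_window = params_window or {}
    members: list[FamilyMember] = []
    for rec in candidates:
        hits = scan_motif(rec, pattern)
        if not hits:
            continue
        params = protein_params(rec, **params_kwargs)
        ok = True
        for name, (lo, hi) in params_window.items():
            value = getattr(params, name)
            if (lo is not None and value < lo) or (hi is not None and value > hi):
                ok = False
                break
        if ok:
            members.append(FamilyMember(record=rec, params=params, hits=hits))
    return members


def members_table(members: Iterable[FamilyMember]):
    """Family members as a table mirroring the survey's gene-information layout."""
    import pandas as pd

    rows = []
    for m in members:
        rows.append({
            "id": m.id,
            "length_aa": m.params.length,
            "mw_kda": round(m.params.mw, 2),
            "pi": round(m.params.pi, 2),
            "tm_count": m.params.tm_count,
            "motif_starts": ";".join(str(h.start) for h in m.hits),
        })
    return pd.DataFrame(
        rows,
        columns=["id", "length_aa", "mw_kda", "pi", "tm_count", "motif_starts"],
    )
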