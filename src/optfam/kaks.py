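"""Nei–Gojobori (1986) Ka/Ks estimation and selection classification.

For each codon, the synonymous site count at a position is the fraction of
viable single-base mutants (mutations creating stop codons are excluded
from the viable set) that preserve the encoded amino acid; per-pair S is
averaged between the two sequences and N = 3·codons − S.  Differences
within a codon are resolved by averaging synonymous/nonsynonymous step
counts over all minimal mutation pathways, excluding pathways that pass
through a stop codon.  The observed proportions ps = Sd/S and pn = Nd/N
are corrected for multiple hits with the Jukes–Cantor transform
d = −(3/4)·ln(1 − (4/3)p), giving Ks and Ka.  Ka/Ks < 1 indicates
purifying selection, = 1 neutral evolution, > 1 positive selection.

This is the classical pathway-counting method (the historical default of
DNA polymorphism packages); no maximum-likelihood ω estimation and no
codon-frequency corrections are attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = "ACGT"


def standard_code() -> dict[str, str]:
    """Codon → amino acid for the standard nuclear code; stops map to '*'."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


STANDARD_CODE = standard_code()


class SaturationError(ValueError):
    """Raised when p ≥ 3/4 makes the Jukes–Cantor correction undefined."""


@dataclass
class CodonPair:
    """An aligned pair of coding sequences, as codon lists with gaps removed."""

    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError(
                f"{self.id_a}/{self.id_b}: unequal codon counts"
            )
        for codons, name in ((self.codons_a, self.id_a), (self.codons_b, self.id_b)):
            for i, c in enumerate(codons):
                if len(c) != 3 or any(b not in BASES for b in c):
                    raise ValueError(f"{name}: bad codon {c!r} at {i}")
                if STANDARD_CODE[c] == "*":
                    raise ValueError(f"{name}: stop codon {c} at {i}")

    def __len__(self) -> int:
        return len(self.codons_a)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ka: float
    Ks: float
    ratio: float | None  # None when Ks == 0
    selection_class: str


_FRACTION_CACHE: dict[str, tuple[float, float, float]] = {}
_PATHWAY_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def syn_site_fractions(
    codon: str, code: Mapping[str, str] | None = None
) -> tuple[float, float, float]:
    """Per-position fraction of viable single-base mutants that are synonymous."""
    if code is None or code is STANDARD_CODE:
        cached = _FRACTION_CACHE.get(codon)
        if cached is not None:
            return cached
    code = code or STANDARD_CODE
    aa = code[codon]
    fractions = []
    for pos in range(3):
        syn = viable = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if code[mutant] == "*":
                continue
            viable += 1
            if code[mutant] == aa:
                syn += 1
        fractions.append(syn / viable if viable else 0.0)
    result = tuple(fractions)
    if code is STANDARD_CODE:
        _FRACTION_CACHE[codon] = result
    return result


def _codon_syn_sites(codon: str, code: Mapping[str, str]) -> float:
    return sum(syn_site_fractions(codon, code))


def _pathway_counts(
    ca: str, cb: str, code: Mapping[str, str]
) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over minimal pathways.

    Pathways that pass through a stop codon are excluded; if every pathway
    is blocked, all pathways are used (stop-traversal tolerated) so the
    differences are still counted.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    if code is STANDARD_CODE:
        cached = _PATHWAY_CACHE.get((ca, cb))
        if cached is not None:
            return cached
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = ca
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if code[nxt] == "*":
                through_stop = True
            if code[nxt] == code[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid or blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    if code is STANDARD_CODE:
        _PATHWAY_CACHE[(ca, cb)] = (sd, nd)
    return sd, nd


def ng86_counts(
    pair: CodonPair, code: Mapping[str, str] | None = None
) -> tuple[float, float, float, float]:
    """Site and difference counts (S, N, Sd, Nd) for an aligned codon pair."""
    code = code or STANDARD_CODE
    s_a = sum(_codon_syn_sites(c, code) for c in pair.codons_a)
    s_b = sum(_codon_syn_sites(c, code) for c in pair.codons_b)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(pair) - S
    Sd = Nd = 0.0
    for ca, cb in zip(pair.codons_a, pair.codons_b):
        sd, nd = _pathway_counts(ca, cb, code)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = −(3/4)·ln(1 − (4/3)·p)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} ≥ 3/4: correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def classify_selection(ratio: float | None, epsilon: float = 0.0) -> str:
    """purifying (<1), neutral (=1 within ±epsilon) or positive (>1)."""
    if ratio is None:
        return "undetermined"
    if ratio < 0:
        raise ValueError("negative Ka/Ks")
    if ratio < 1.0 - epsilon:
        return "purifying"
    if ratio > 1.0 + epsilon:
        return "positive"
    return "neutral"


def kaks_estimate(
    counts: tuple[float, float, float, float], epsilon: float = 0.0
) -> KaKsResult:
    """Ka, Ks and Ka/Ks from (S, N, Sd, Nd) counts."""
    S, N, Sd, Nd = counts
    if S <= 0 or N <= 0:
        raise ValueError("S and N must be positive")
    ps, pn = Sd / S, Nd / N
    Ks, Ka = jukes_cantor(ps), jukes_cantor(pn)
    ratio = Ka / Ks if Ks > 0 else None
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ka=Ka, Ks=Ks, ratio=ratio,
        selection_class=classify_selection(ratio, epsilon),
    )


def pair_kaks(
    pair: CodonPair, code: Mapping[str, str] | None = None,
    epsilon: float = 0.0,
) -> KaKsResult:
    return kaks_estimate(ng86_counts(pair, code), epsilon)


def back_translate_align(
    protein_alignment,
    cds: Mapping[str, str],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[CodonPair]:
    """Map an aligned protein pair back onto its source codons.

    Each ungapped protein row must translate exactly from its CDS under
    the standard code (a terminal stop codon is trimmed).  Aligned columns
    where either member carries a gap are dropped, as are columns with
    ambiguous or stop codons, yielding codon pairs ready for counting.
    """
    index = {t: i for i, t in enumerate(protein_alignment.taxa)}
    codon_rows: dict[str, list[str | None]] = {}
    for taxon in protein_alignment.taxa:
        if taxon not in cds:
            raise KeyError(f"no CDS for {taxon}")
        seq = cds[taxon].upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"{taxon}: CDS length {len(seq)} not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and STANDARD_CODE.get(codons[-1]) == "*":
            codons = codons[:-1]
        translated = str(Seq("".join(codons)).translate())
        row = protein_alignment.rows[index[taxon]]
        ungapped = row.replace("-", "")
        if len(translated) != len(ungapped):
            raise ValueError(
                f"{taxon}: CDS translates to {len(translated)} aa but aligned "
                f"row has {len(ungapped)}"
            )
        for pos, (aa_t, aa_p) in enumerate(zip(translated, ungapped), 1):
            if aa_t != aa_p.upper():
                raise ValueError(
                    f"{taxon}: translation mismatch at residue {pos} "
                    f"({aa_t} vs {aa_p})"
                )
        aligned: list[str | None] = []
        k = 0
        for ch in row:
            if ch == "-":
                aligned.append(None)
            else:
                aligned.append(codons[k])
                k += 1
        codon_rows[taxon] = aligned
    if pairs is None:
        taxa = protein_alignment.taxa
        pairs = [(taxa[i], taxa[j]) for i in range(len(taxa))
                 for j in range(i + 1, len(taxa))]
    out = []
    for a, b in pairs:
        if a not in codon_rows or b not in codon_rows:
            missing = a if a not in codon_rows else b
            raise KeyError(f"{missing} not in alignment")
        ca, cb = [], []
        for x, y in zip(codon_rows[a], codon_rows[b]):
            if x is None or y is None:
                continue
            if any(ch not in BASES for ch in x + y):
                continue
            if STANDARD_CODE[x] == "*" or STANDARD_CODE[y] == "*":
                continue
            ca.append(x)
            cb.append(y)
        out.append(CodonPair(id_a=a, id_b=b, codons_a=ca, codons_b=cb))
    return out
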