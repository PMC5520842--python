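"""Synthetic-data generators with controlled ground truth.

Three generators emulate the statistical structure the pipeline assumes,
so every stage can be exercised and scored without any database access:

* codon-pair evolution at a specified synonymous divergence (Ks) and
  Ka/Ks (ω), by sequential single-base mutation with stop rejection and
  ω-weighted acceptance of nonsynonymous changes;
* chromosome gene maps with planted tandem arrays and duplicated
  collinear segments;
* MPSS-like tag-count matrices with planted fold responses under Poisson
  sampling noise (tags are counts of independent signatures, so Poisson —
  not negative-binomial — noise matches the sampling character).

All generators are deterministic under a fixed seed, and each returns a
truth record sufficient to score the downstream calls without re-deriving
them.  Realized (not target) divergence is the scoring truth for codon
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from optfam.duplication import GeneLocus
from optfam.kaks import BASES, STANDARD_CODE, _codon_syn_sites

SENSE_CODONS = sorted(c for c, aa in STANDARD_CODE.items() if aa != "*")

#: Above this target the synonymous signal is close to saturation and the
#: Jukes–Cantor correction becomes numerically meaningless.
MAX_TARGET_KS = 2.5


@dataclass
class CodonPairSim:
    cds_a: str
    cds_b: str
    syn_events: int
    nonsyn_events: int
    S0: float
    N0: float

    @property
    def realized_omega(self) -> float | None:
        """Rate per nonsynonymous site over rate per synonymous site."""
        if self.syn_events == 0:
            return None
        return (self.nonsyn_events / self.N0) / (self.syn_events / self.S0)


def simulate_codon_pair(
    n_codons: int,
    target_ks: float,
    omega: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CodonPairSim:
    """Evolve two copies of a random ancestral CDS to a target Ks at a given ω.

    Single-base mutations are proposed uniformly (random codon, position
    and alternative base) on a randomly chosen lineage; proposals creating
    stop codons are rejected outright, synonymous changes are accepted
    with relative probability 1 and nonsynonymous changes with relative
    probability ω.  Evolution stops when the number of accepted
    synonymous events reaches target_ks × (ancestral synonymous sites).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be ≥ 1")
    if target_ks < 0 or omega < 0:
        raise ValueError("target_ks and omega must be ≥ 0")
    if target_ks > MAX_TARGET_KS:
        raise ValueError(
            f"target_ks {target_ks} exceeds {MAX_TARGET_KS}: synonymous "
            "sites would saturate"
        )
    rng = rng or np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    S0 = sum(_codon_syn_sites(c, STANDARD_CODE) for c in ancestor)
    N0 = 3.0 * n_codons - S0
    target_syn = int(round(target_ks * S0))
    p_syn = 1.0 if omega <= 1 else 1.0 / omega
    p_nonsyn = omega if omega <= 1 else 1.0
    lineages = [list(ancestor), list(ancestor)]
    syn_events = nonsyn_events = 0
    while syn_events < target_syn:
        seq = lineages[int(rng.integers(0, 2))]
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        codon = seq[ci]
        alternatives = [b for b in BASES if b != codon[pos]]
        mutant = codon[:pos] + alternatives[int(rng.integers(0, 3))] + codon[pos + 1 :]
        if STANDARD_CODE[mutant] == "*":
            continue
        synonymous = STANDARD_CODE[mutant] == STANDARD_CODE[codon]
        accept_p = p_syn if synonymous else p_nonsyn
        if accept_p < 1.0 and rng.random() >= accept_p:
            continue
        seq[ci] = mutant
        if synonymous:
            syn_events += 1
        else:
            nonsyn_events += 1
    return CodonPairSim(
        cds_a="".join(lineages[0]),
        cds_b="".join(lineages[1]),
        syn_events=syn_events,
        nonsyn_events=nonsyn_events,
        S0=S0,
        N0=N0,
    )


@dataclass
class GeneMapSim:
    loci: dict[str, GeneLocus]
    anchors: list[tuple[GeneLocus, GeneLocus]]
    truth: list[tuple[str, str, str]]  # (id_a, id_b, mechanism)


def simulate_gene_map(
    chromosomes: Mapping[str, int],
    tandem_pairs: Sequence[tuple[str, int]] = (),
    segmental_blocks: Sequence[tuple[str, str, int]] = (),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    gene_length: tuple[int, int] = (2_000, 6_000),
    intergenic: tuple[int, int] = (5_000, 40_000),
) -> GeneMapSim:
    """Ranked, non-overlapping gene coordinates with planted duplications.

    ``tandem_pairs`` plants one pair per ``(chromosome, intervening)``
    entry; ``segmental_blocks`` plants one collinear block per
    ``(chrom_a, chrom_b, n_anchors)`` entry, pairing runs of consecutive
    genes (with the generator's intergenic spacing, consecutive anchors sit
    well inside the 100 kb collinearity gap).  Every planted pair is listed
    in the truth record with its mechanism.
    """
    rng = rng or np.random.default_rng(seed)
    loci: dict[str, GeneLocus] = {}
    by_chrom: dict[str, list[GeneLocus]] = {}
    for chrom in sorted(chromosomes):
        n = chromosomes[chrom]
        pos = 1
        genes = []
        for i in range(n):
            pos += int(rng.integers(*intergenic))
            length = int(rng.integers(*gene_length))
            gid = f"{chrom}_g{i + 1:03d}"
            locus = GeneLocus(
                id=gid, chromosome=chrom, start=pos, end=pos + length,
                strand="+" if rng.random() < 0.5 else "-", rank=i + 1,
            )
            genes.append(locus)
            loci[gid] = locus
            pos += length
        by_chrom[chrom] = genes
    truth: list[tuple[str, str, str]] = []
    for chrom, intervening in tandem_pairs:
        genes = by_chrom[chrom]
        span = intervening + 1
        if span >= len(genes):
            raise ValueError(
                f"cannot plant tandem pair with {intervening} intervening "
                f"genes on {chrom} ({len(genes)} genes)"
            )
        r = int(rng.integers(0, len(genes) - span))
        truth.append((genes[r].id, genes[r + span].id, "tandem"))
    anchors: list[tuple[GeneLocus, GeneLocus]] = []
    for chrom_a, chrom_b, n_anchors in segmental_blocks:
        ga, gb = by_chrom[chrom_a], by_chrom[chrom_b]
        if n_anchors > min(len(ga), len(gb)):
            raise ValueError("not enough genes to plant the requested block")
        ra = int(rng.integers(0, len(ga) - n_anchors + 1))
        rb = int(rng.integers(0, len(gb) - n_anchors + 1))
        if chrom_a == chrom_b and abs(ra - rb) < n_anchors:
            raise ValueError("self-overlapping block on one chromosome")
        for k in range(n_anchors):
            a, b = ga[ra + k], gb[rb + k]
            anchors.append((a, b))
            truth.append((a.id, b.id, "segmental"))
    return GeneMapSim(loci=loci, anchors=anchors, truth=truth)


DEFAULT_TISSUE_LIBRARIES = ("root_14d", "leaf_14d", "root_60d", "leaf_60d", "callus")
DEFAULT_STRESS_CLASSES = ("Salt", "Drought", "Cold", "X. oryzae", "M. grisea")

#: Default planted effect size: a four-fold abundance change, comfortably
#: past the inclusive two-fold call boundary (an exactly-two-fold planting
#: sits on the boundary, where sampling noise alone decides the call).
DEFAULT_PLANTED_FOLD = 4.0


@dataclass(frozen=True)
class PlantedResponse:
    gene: str
    condition_class: str  # one of the stress classes, or "Tissues"
    fold: float = DEFAULT_PLANTED_FOLD
    baseline_tpm: float | None = None


@dataclass
class ExpressionSim:
    counts: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame
    baselines: pd.Series = field(repr=False, default=None)


def simulate_expression(
    n_genes: int = 50,
    planted: Sequence[PlantedResponse] = (),
    depth: int = 1_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    tissue_libraries: Sequence[str] = DEFAULT_TISSUE_LIBRARIES,
    stress_classes: Sequence[str] = DEFAULT_STRESS_CLASSES,
    baseline_log_mean: float = np.log(30.0),
    baseline_log_sigma: float = 1.0,
) -> ExpressionSim:
    """MPSS-like tag-count matrix with planted responses.

    Per-gene baseline abundance (tpm) is log-normal (heavy-tailed,
    positive); each stress class gets a control and a treatment library,
    and planted genes have their treatment abundance multiplied by the
    planted fold.  A ``Tissues`` planting silences the gene in one tissue
    library instead (a presence difference).  Tag counts are Poisson at
    the library depth; a ``background`` row absorbs the remaining depth so
    tpm values of simulated genes sit at their planted scale.
    """
    rng = rng or np.random.default_rng(seed)
    genes = [f"gene{i + 1:03d}" for i in range(n_genes)]
    baselines = pd.Series(
        rng.lognormal(baseline_log_mean, baseline_log_sigma, n_genes),
        index=genes,
    )
    for p in planted:
        if p.gene not in baselines.index:
            raise KeyError(f"planted gene {p.gene} not in matrix")
        if p.baseline_tpm is not None:
            baselines[p.gene] = p.baseline_tpm
    meta_rows = []
    for lib in tissue_libraries:
        meta_rows.append((lib, lib.split("_")[0], "Tissues", ""))
    for cls in stress_classes:
        tag = cls.lower().replace(" ", "_").replace(".", "")
        meta_rows.append((f"{tag}_control", "seedling", cls, ""))
        meta_rows.append((f"{tag}_treatment", "seedling", cls, f"{tag}_control"))
    meta = pd.DataFrame(
        meta_rows, columns=["library", "tissue", "class", "control_library"]
    ).set_index("library")
    expected = pd.DataFrame(
        np.tile(baselines.to_numpy()[:, None], (1, len(meta))),
        index=genes, columns=meta.index,
    )
    truth_rows = []
    for p in planted:
        if p.condition_class == "Tissues":
            lib = tissue_libraries[int(rng.integers(0, len(tissue_libraries)))]
            expected.at[p.gene, lib] *= p.fold
            truth_rows.append({
                "gene": p.gene, "class": "Tissues", "library": lib,
                "fold": p.fold,
                "call": "present" if p.fold >= 1 else "absent",
            })
        else:
            if p.condition_class not in stress_classes:
                raise ValueError(f"unknown condition class {p.condition_class!r}")
            tag = p.condition_class.lower().replace(" ", "_").replace(".", "")
            lib = f"{tag}_treatment"
            expected.at[p.gene, lib] *= p.fold
            truth_rows.append({
                "gene": p.gene, "class": p.condition_class, "library": lib,
                "fold": p.fold, "call": "up" if p.fold > 1 else "down",
            })
    lam = expected * depth / 1e6
    counts = pd.DataFrame(
        rng.poisson(lam.to_numpy()), index=genes, columns=meta.index
    )
    background = np.maximum(depth - lam.sum(axis=0).to_numpy(), 0.0)
    counts.loc["background"] = rng.poisson(background)
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "class", "library", "fold", "call"]
    )
    return ExpressionSim(counts=counts, meta=meta, truth=truth, baselines=baselines)
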