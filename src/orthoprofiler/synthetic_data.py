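"""Synthetic datasets with planted, recoverable structure.

Real inputs for a conservation-profiling study — curated gene sets,
ortholog tables from orthology databases, proteomes, an ontology and
expression annotations — all require downloads.  This module fabricates
desk-scale stand-ins with known ground truth instead:

* a reference ("human") proteome of random protein sequences;
* orthologs diverged from it along a star phylogeny, where each species has
  a branch length (expected substitutions per site) and each gene belongs
  to a conservation *tier* that scales that rate and may delete the gene
  outright in some species groups — mirroring the empirical pattern that
  lineage-restricted genes show zero similarity in distant organisms;
* a rooted ontology DAG with terms at controlled depths, plus gene→term and
  gene→tissue annotation tables in which chosen terms are planted into
  chosen tiers on top of a uniform background rate.

Everything is driven by a single integer seed, and identical configs give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from orthoprofiler.alignment import write_fasta

__all__ = [
    "AMINO_ACIDS",
    "ABSENT",
    "SpeciesSpec",
    "GeneTierSpec",
    "SimulationConfig",
    "default_config",
    "simulate_reference_proteome",
    "evolve_ortholog",
    "simulate_dataset",
    "simulate_ontology_and_annotations",
    "default_ontology_config",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: sentinel returned when a gene has no ortholog in a species
ABSENT = None


@dataclass(frozen=True)
class SpeciesSpec:
    """One target organism on the mock phylogeny.

    ``group`` labels the complexity stratum the organism belongs to (the
    planted column-cluster identity); ``branch_length`` is the expected
    number of substitutions per site separating it from the reference.
    """

    name: str
    group: str
    branch_length: float

    def __post_init__(self):
        if self.branch_length < 0:
            raise ValueError(f"branch_length must be >= 0, got {self.branch_length}")


@dataclass(frozen=True)
class GeneTierSpec:
    """One conservation tier (the planted row-cluster identity).

    ``rate_multiplier`` scales each species' branch length for genes of
    this tier; ``loss_probability`` maps a species *group* to the chance
    that genes of this tier have no ortholog there at all.
    """

    tier: str
    rate_multiplier: float
    loss_probability: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.rate_multiplier <= 0:
            raise ValueError(f"rate_multiplier must be > 0, got {self.rate_multiplier}")
        for group, p in self.loss_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"loss_probability[{group!r}] = {p} outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 60
    protein_length: int = 200
    species: Sequence[SpeciesSpec] = ()
    tiers: Sequence[GeneTierSpec] = ()
    indel_rate: float = 0.01
    duplicate_probability: float = 0.0
    seed: int = 42

    def __post_init__(self):
        if self.n_genes <= 0 or self.protein_length <= 0:
            raise ValueError("n_genes and protein_length must be positive")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")


def default_config(seed: int = 42) -> SimulationConfig:
    """The default study conditions: 9 organisms in 3 complexity groups,
    60 genes in 4 conservation tiers.

    Branch lengths place the groups at well-separated distances from the
    reference; the two least-conserved tiers are additionally deleted from
    the more distant groups, reproducing the block of zero-similarity cells
    that dominates the lower rows of the empirical heatmap.
    """
    species = [
        SpeciesSpec("sp_high1", "high", 0.10),
        SpeciesSpec("sp_high2", "high", 0.15),
        SpeciesSpec("sp_high3", "high", 0.20),
        SpeciesSpec("sp_med1", "medium", 0.55),
        SpeciesSpec("sp_med2", "medium", 0.65),
        SpeciesSpec("sp_med3", "medium", 0.75),
        SpeciesSpec("sp_low1", "low", 1.30),
        SpeciesSpec("sp_low2", "low", 1.45),
        SpeciesSpec("sp_low3", "low", 1.60),
    ]
    tiers = [
        GeneTierSpec("I", 0.30),
        GeneTierSpec("II", 1.00),
        GeneTierSpec("III", 1.60, {"low": 1.0}),
        GeneTierSpec("IV", 2.20, {"medium": 1.0, "low": 1.0}),
    ]
    return SimulationConfig(n_genes=60, protein_length=200, species=species,
                            tiers=tiers, indel_rate=0.01, seed=seed)


def simulate_reference_proteome(config: SimulationConfig) -> list[tuple[str, str]]:
    """Draw the reference proteome: ``n_genes`` i.i.d. uniform-residue
    sequences of ``protein_length``, deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    records = []
    for g in range(config.n_genes):
        seq = "".join(rng.choice(aa, size=config.protein_length))
        records.append((f"gene{g:03d}", seq))
    return records


def evolve_ortholog(reference_seq: str, branch_length: float, rate_multiplier: float,
                    indel_rate: float, rng: np.random.Generator,
                    loss_probability: float = 0.0) -> str | None:
    """Evolve one ortholog from the reference, or delete it.

    With probability ``loss_probability`` returns :data:`ABSENT` (``None``).
    Otherwise applies ``Poisson(branch_length * rate_multiplier * L)`` point
    substitutions at uniform positions (replacement uniform over the other
    19 residues; sites may be hit repeatedly, so identity saturates rather
    than going to zero), then ``Poisson(indel_rate * L)`` single-residue
    insertions or deletions.
    """
    if not reference_seq:
        raise ValueError("reference sequence must be non-empty")
    if branch_length < 0 or rate_multiplier < 0 or indel_rate < 0:
        raise ValueError("rates must be non-negative")
    if loss_probability and rng.random() < loss_probability:
        return ABSENT
    length = len(reference_seq)
    seq = list(reference_seq)
    n_subs = rng.poisson(branch_length * rate_multiplier * length)
    for _ in range(n_subs):
        pos = rng.integers(length)
        current = seq[pos]
        choices = AMINO_ACIDS.replace(current, "") if current in AMINO_ACIDS else AMINO_ACIDS
        seq[pos] = choices[rng.integers(len(choices))]
    n_indels = rng.poisson(indel_rate * length)
    for _ in range(n_indels):
        if len(seq) > 1 and rng.random() < 0.5:
            del seq[rng.integers(len(seq))]
        else:
            pos = rng.integers(len(seq) + 1)
            seq.insert(pos, AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
    return "".join(seq)


@dataclass(frozen=True)
class SimulatedDataset:
    """In-memory view of one simulated study; see :func:`simulate_dataset`."""

    reference: list[tuple[str, str]]
    proteomes: dict[str, list[tuple[str, str]]]  # species -> records
    ortholog_table: list[tuple[str, str, str]]   # (human_gene, species, ortholog_id)
    tier_of_gene: dict[str, str]
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Simulate the full study and optionally write it to ``out_dir``.

    Genes are assigned to tiers in contiguous blocks of ``n_genes /
    n_tiers`` (remainder to the last tier).  Absent orthologs are simply
    omitted from the ortholog table.  When ``duplicate_probability`` > 0 a
    second, independently evolved ortholog is emitted for some (gene,
    species) pairs, to exercise downstream best-hit handling.

    Files written: ``human.fasta``, ``<species>.fasta`` per organism,
    ``orthologs.tsv`` (``human_gene\tspecies\tortholog_id``) and
    ``tiers.tsv`` (``gene\ttier``).
    """
    if not config.species or not config.tiers:
        raise ValueError("config must define at least one species and one tier")
    reference = simulate_reference_proteome(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n_tiers = len(config.tiers)
    block = config.n_genes // n_tiers
    tier_of_gene: dict[str, str] = {}
    gene_tier_spec: dict[str, GeneTierSpec] = {}
    for idx, (gene, _) in enumerate(reference):
        t = config.tiers[min(idx // block, n_tiers - 1)] if block else config.tiers[-1]
        tier_of_gene[gene] = t.tier
        gene_tier_spec[gene] = t

    proteomes: dict[str, list[tuple[str, str]]] = {}
    table: list[tuple[str, str, str]] = []
    for sp in config.species:
        records: list[tuple[str, str]] = []
        for gene, seq in reference:
            tspec = gene_tier_spec[gene]
            loss = tspec.loss_probability.get(sp.group, 0.0)
            n_copies = 1
            if config.duplicate_probability and rng.random() < config.duplicate_probability:
                n_copies = 2
            for copy in range(n_copies):
                evolved = evolve_ortholog(seq, sp.branch_length, tspec.rate_multiplier,
                                          config.indel_rate, rng, loss_probability=loss)
                if evolved is ABSENT:
                    break  # lost in this species: no copies at all
                oid = f"{sp.name}|{gene}" if copy == 0 else f"{sp.name}|{gene}.{copy}"
                records.append((oid, evolved))
                table.append((gene, sp.name, oid))
        proteomes[sp.name] = records

    ds = SimulatedDataset(reference=reference, proteomes=proteomes,
                          ortholog_table=table, tier_of_gene=tier_of_gene,
                          config=config)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SimulatedDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.reference, out_dir / "human.fasta")
    for sp, records in ds.proteomes.items():
        write_fasta(records, out_dir / f"{sp}.fasta")
    with open(out_dir / "orthologs.tsv", "w") as fh:
        fh.write("human_gene\tspecies\tortholog_id\n")
        for row in ds.ortholog_table:
            fh.write("\t".join(row) + "\n")
    with open(out_dir / "tiers.tsv", "w") as fh:
        fh.write("gene\ttier\n")
        for gene, tier in ds.tier_of_gene.items():
            fh.write(f"{gene}\t{tier}\n")


# ---------------------------------------------------------------------------
# ontology + annotations


@dataclass(frozen=True)
class SimulatedAnnotations:
    """Toy ontology DAG plus annotation tables with planted enrichments."""

    edges: list[tuple[str, str]]          # (child, parent)
    annotations: list[tuple[str, str]]    # (gene, term), leaf-most only
    tissues: list[tuple[str, str]]        # (gene, tissue)
    planted: Mapping[str, str]            # tier -> planted term
    planted_tissue: Mapping[str, str]     # tier -> planted tissue


def default_ontology_config() -> dict:
    """Depth profile and planting used by the default pipeline run: a DAG
    spanning depths 1-6 with six terms per depth, one planted term per tier
    at depth 4 or 5 (inside the default reporting window)."""
    return {
        "n_terms": 36,
        "depth_profile": {1: 6, 2: 6, 3: 6, 4: 6, 5: 6, 6: 6},
        "background_rate": 0.05,
    }


def simulate_ontology_and_annotations(
    n_terms: int,
    depth_profile: Mapping[int, int],
    genes: Sequence[str],
    planted: Mapping[str, str] | None = None,
    background_rate: float = 0.05,
    seed: int = 0,
    *,
    tier_of_gene: Mapping[str, str] | None = None,
    planted_probability: float = 0.9,
    planted_tissue: Mapping[str, str] | None = None,
    tissue_labels: Sequence[str] = ("kidney", "nervous_system", "adrenal", "pancreas", "liver"),
    tissue_background_rate: float = 0.1,
    out_dir: str | Path | None = None,
) -> SimulatedAnnotations:
    """Build a rooted toy ontology and annotation tables.

    The DAG has a single root ``T_root`` (depth 0) and ``depth_profile[d]``
    terms at each depth ``d``; every term's parents sit exactly one level
    up, so shortest-path depth equals the construction level.  Occasional
    second parents (same level up) make it a genuine DAG rather than a tree.

    ``planted`` maps a tier label to a term id (e.g. ``"I" -> "T_d4_0"``);
    each gene of that tier is annotated to the term with probability
    ``planted_probability`` (>= 0.8 by default).  Every gene is annotated
    to each background term with probability ``background_rate``.
    Annotations are written to the named (leaf-most) term only — ancestral
    closure is the enrichment stage's job.  Tissue labels are flat
    categories planted the same way.
    """
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must lie in [0, 1]")
    planted = dict(planted or {})
    planted_tissue = dict(planted_tissue or {})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    levels: dict[int, list[str]] = {0: ["T_root"]}
    edges: list[tuple[str, str]] = []
    total = 1
    for depth in sorted(depth_profile):
        count = depth_profile[depth]
        if depth < 1:
            raise ValueError("depth_profile keys must be >= 1")
        names = [f"T_d{depth}_{i}" for i in range(count)]
        parents = levels.get(depth - 1)
        if not parents:
            raise ValueError(f"depth_profile has a gap below depth {depth}")
        for name in names:
            edges.append((name, parents[int(rng.integers(len(parents)))]))
            if len(parents) > 1 and rng.random() < 0.3:
                other = parents[int(rng.integers(len(parents)))]
                if (name, other) not in edges:
                    edges.append((name, other))
        levels[depth] = names
        total += count
        if total - 1 >= n_terms:
            break

    all_terms = [t for terms in levels.values() for t in terms]
    for tier, term in planted.items():
        if term not in all_terms:
            raise ValueError(f"planted term {term!r} for tier {tier!r} is not in the DAG")

    # Background annotations avoid the planted terms AND their descendant
    # subtrees: the true-path rule would otherwise funnel background signal
    # up into a planted term and dilute the planted contrast.
    planted_terms = set(planted.values())
    child_of: dict[str, list[str]] = {}
    for child, parent in edges:
        child_of.setdefault(parent, []).append(child)
    blocked = set(planted_terms)
    stack = list(planted_terms)
    while stack:
        for c in child_of.get(stack.pop(), ()):
            if c not in blocked:
                blocked.add(c)
                stack.append(c)
    background_terms = [t for t in all_terms if t != "T_root" and t not in blocked]

    annotations: list[tuple[str, str]] = []
    tissues: list[tuple[str, str]] = []
    tier_of_gene = tier_of_gene or {}
    for gene in genes:
        tier = tier_of_gene.get(gene)
        if tier is not None and tier in planted:
            if rng.random() < planted_probability:
                annotations.append((gene, planted[tier]))
        for term in background_terms:
            if rng.random() < background_rate:
                annotations.append((gene, term))
        if tier is not None and tier in planted_tissue:
            tissues.append((gene, planted_tissue[tier]))
        for lab in tissue_labels:
            if rng.random() < tissue_background_rate:
                tissues.append((gene, lab))

    result = SimulatedAnnotations(edges=edges, annotations=annotations,
                                  tissues=tissues, planted=planted,
                                  planted_tissue=planted_tissue)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "ontology_edges.tsv", "w") as fh:
            fh.write("child\tparent\n")
            for child, parent in edges:
                fh.write(f"{child}\t{parent}\n")
        with open(out_dir / "annotations.tsv", "w") as fh:
            fh.write("gene\tterm\n")
            for gene, term in annotations:
                fh.write(f"{gene}\t{term}\n")
        with open(out_dir / "tissues.tsv", "w") as fh:
            fh.write("gene\ttissue\n")
            for gene, tissue in tissues:
                fh.write(f"{gene}\t{tissue}\n")
    return result


def default_planted_terms() -> dict[str, str]:
    """Planted term per tier, all inside the depth 4-5 reporting window.

    Four distinct depth-4 terms: being at one depth they cannot be
    ancestors of one another, so the true-path closure cannot leak one
    tier's planted signal into another tier's planted term.
    """
    return {"I": "T_d4_0", "II": "T_d4_1", "III": "T_d4_2", "IV": "T_d4_3"}


def default_planted_tissues() -> dict[str, str]:
    """Planted tissue per tier: conserved tiers in excretory/endocrine
    organs, lineage-restricted tiers in nervous tissue — the qualitative
    pattern the empirical expression analysis shows."""
    return {"I": "kidney", "II": "adrenal", "III": "nervous_system", "IV": "nervous_system"}
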