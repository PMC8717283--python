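"""Synthetic genomes, gene-family histories and codon alignments with truth.

The generator plants taste-receptor-like single-exon ORFs into random
contigs, recording every planted gene (interval, strand, category,
engineered disruptions) in a :class:`TruthTable`, so the mining pipeline can
be scored against known truth.  It also simulates gene-family birth--death
histories along a species tree and codon alignments under site-wise dN/dS,
for validating the reconciliation and selection stages.

Design of the planted receptors
-------------------------------
Intact plants are built from template proteins with the shape of a 7-TM
GPCR: seven hydrophobic blocks of 19--23 residues drawn from {I,L,V,F,A}
separated by strongly hydrophilic loops, so a Kyte--Doolittle screen finds
at least seven transmembrane segments by construction.  Protein lengths are
drawn so the coding sequence (incl. stop) spans 816--1272 nt, the length
range of intact bitter-receptor genes.  Divergence from the query templates
is applied at the protein level (hydrophobic positions stay hydrophobic)
and back-translated with uniform codon choice, which preserves both the ORF
and the hydropathy profile.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np

from ._codons import (
    AA_TO_CODONS,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    revcomp,
    translate,
)

HYDROPHOBIC = "ILVFA"
HYDROPHILIC = "DEKRNQSGPH"

# intact CDS length range in nt, including the stop codon
MIN_CDS_NT = 816
MAX_CDS_NT = 1272


class SimulationError(ValueError):
    """Raised when a SimSpec cannot be realised (genes do not fit, etc.)."""


@dataclass
class SimSpec:
    """Parameters of a synthetic genome.

    divergence is the expected fraction of protein residues substituted
    between a planted gene and the query template it derives from.
    """

    n_intact: int = 20
    n_partial: int = 5
    n_pseudo: int = 5
    n_contigs: int | None = None  # None: one contig per gene + 3 empty
    contig_len: int = 6000
    divergence: float = 0.1
    gc: float = 0.42
    seed: int = 0
    n_queries: int = 6
    family: str = "Tas2r"
    margin: int = 600  # clearance between a non-partial plant and contig end
    with_markers: bool = True

    def __post_init__(self) -> None:
        if min(self.n_intact, self.n_partial, self.n_pseudo) < 0:
            raise SimulationError("gene counts must be >= 0")
        if not 0.0 <= self.divergence < 1.0:
            raise SimulationError("divergence must be in [0, 1)")
        if not 0.0 < self.gc < 1.0:
            raise SimulationError("gc must be in (0, 1)")


@dataclass
class TruthRecord:
    """One planted gene: 0-based half-open interval on the forward strand."""

    gene_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    category: str  # INTACT | PARTIAL | PSEUDO
    family: str
    disruptions: list = field(default_factory=list)  # (kind, position) pairs


@dataclass
class MarkerPlacement:
    marker: str
    contig_id: str
    start: int
    end: int


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)
    markers: list[MarkerPlacement] = field(default_factory=list)

    def by_category(self, category: str) -> list[TruthRecord]:
        return [r for r in self.records if r.category == category]

    def to_gff3(self) -> str:
        """GFF3 (1-based inclusive) of the planted genes."""
        lines = ["##gff-version 3"]
        for r in self.records:
            attrs = f"ID={r.gene_id};category={r.category};family={r.family}"
            lines.append(
                "\t".join(
                    [
                        r.contig_id,
                        "tastemine_sim",
                        "gene",
                        str(r.start + 1),
                        str(r.end),
                        ".",
                        r.strand,
                        ".",
                        attrs,
                    ]
                )
            )
        return "\n".join(lines) + "\n"


@dataclass
class GenomeAssembly:
    """Contig set; sequences are plain uppercase ACGT strings."""

    contigs: dict[str, str]

    def to_fasta(self) -> str:
        out = io.StringIO()
        for name, seq in self.contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")
        return out.getvalue()


# ---------------------------------------------------------------------------
# template / plant construction
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def make_template_protein(rng: np.random.Generator) -> str:
    """A 7-TM-shaped protein of 271--423 aa (CDS 816--1272 nt with stop)."""
    target = int(rng.integers(MIN_CDS_NT // 3 - 1, MAX_CDS_NT // 3))  # 271..423
    parts = ["M"]
    parts.append(_rand_from(rng, HYDROPHILIC, int(rng.integers(10, 18))))
    for _ in range(7):
        parts.append(_rand_from(rng, HYDROPHOBIC, int(rng.integers(19, 24))))
        parts.append(_rand_from(rng, HYDROPHILIC, int(rng.integers(10, 18))))
    prot = "".join(parts)
    if len(prot) < target:
        prot += _rand_from(rng, HYDROPHILIC, target - len(prot))
    return prot[:target] if len(prot) > target else prot


def _rand_from(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def diverge_protein(
    protein: str, divergence: float, rng: np.random.Generator
) -> str:
    """Substitute ~divergence of residues, class-preserving, Met1 fixed."""
    if divergence == 0.0:
        return protein
    n_sub = int(round(divergence * (len(protein) - 1)))
    positions = rng.choice(np.arange(1, len(protein)), size=n_sub, replace=False)
    out = list(protein)
    for pos in positions:
        pool = HYDROPHOBIC if out[pos] in HYDROPHOBIC else HYDROPHILIC
        choices = [a for a in pool if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform codon choice per residue; no stop appended."""
    return "".join(
        AA_TO_CODONS[aa][int(rng.integers(len(AA_TO_CODONS[aa])))]
        for aa in protein
    )


def make_orf(protein: str, rng: np.random.Generator) -> str:
    """Complete CDS: back-translated protein plus one random stop codon."""
    return back_translate(protein, rng) + STOP_CODONS[int(rng.integers(3))]


def mutate_to_pseudogene(
    orf: str, n_disruptions: int, seed: int | np.random.Generator
):
    """Engineer premature stops and/or 1--2 nt indels into a complete ORF.

    Returns (mutated sequence, disruption list) where each disruption is a
    (kind, position) pair; stop positions are 0-based codon indices in the
    original ORF, indel positions 0-based nt offsets.  The start codon is
    never touched.
    """
    if n_disruptions < 1:
        raise ValueError("n_disruptions must be >= 1")
    if len(orf) % 3 != 0 or orf[:3] != "ATG":
        raise ValueError("input must be a complete ORF starting with ATG")
    if translate(orf)[-1] != "*":
        raise ValueError("input ORF must end with a stop codon")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_codons = len(orf) // 3
    # keep disruptions away from the termini so truncated proteins are
    # clearly premature and indels sit inside alignable sequence
    lo, hi = max(2, n_codons // 10), n_codons - max(2, n_codons // 10)
    codon_positions = sorted(
        int(c) for c in rng.choice(np.arange(lo, hi), n_disruptions, replace=False)
    )
    plan = []
    for cpos in codon_positions:
        kind = "PREMATURE_STOP" if rng.random() < 0.5 else "FRAMESHIFT"
        plan.append((cpos, kind))
    seq = orf
    disruptions = []
    # apply right-to-left so recorded (original-coordinate) positions hold
    for cpos, kind in reversed(plan):
        if kind == "PREMATURE_STOP":
            stop = STOP_CODONS[int(rng.integers(3))]
            seq = seq[: 3 * cpos] + stop + seq[3 * cpos + 3 :]
            disruptions.append((kind, cpos))
        else:
            nt = 3 * cpos + int(rng.integers(3))
            indel_len = int(rng.integers(1, 3))
            if rng.random() < 0.5:  # deletion
                seq = seq[:nt] + seq[nt + indel_len :]
            else:  # insertion
                ins = _rand_from(rng, "ACGT", indel_len)
                seq = seq[:nt] + ins + seq[nt:]
            disruptions.append((kind, nt))
    disruptions.reverse()
    return seq, disruptions


def mutate_to_pseudogene_seq(orf, n_disruptions, seed):
    """Sequence-only convenience wrapper around :func:`mutate_to_pseudogene`."""
    return mutate_to_pseudogene(orf, n_disruptions, seed)[0]


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


def simulate_queries(spec: SimSpec) -> dict[str, str]:
    """The query protein panel; plants derive from these templates."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    return {
        f"{spec.family}_query{i + 1}": make_template_protein(rng)
        for i in range(spec.n_queries)
    }


def simulate_decoys(spec: SimSpec, n: int = 4, family: str = "V2R") -> dict[str, str]:
    """Decoy receptor panel for reciprocal verification (unrelated seed
    stream, same architecture so decoys are plausible GPCRs)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 99]))
    return {f"{family}_decoy{i + 1}": make_template_protein(rng) for i in range(n)}


def simulate_genome(spec: SimSpec):
    """Generate a genome with planted genes.  Returns (assembly, truth).

    Plants (in order): intact genes, pseudogenes (1--2 disruptions each),
    contig-edge partial genes.  One plant per contig; remaining contigs are
    pure background.  Marker genes for the synteny stage are recorded as
    annotations on two dedicated contigs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    queries = simulate_queries(spec)
    query_names = list(queries)

    n_genes = spec.n_intact + spec.n_pseudo + spec.n_partial
    n_marker_contigs = 1 if spec.with_markers else 0
    n_contigs = (
        spec.n_contigs if spec.n_contigs is not None else n_genes + 3 + n_marker_contigs
    )
    if n_contigs < n_genes + n_marker_contigs:
        raise SimulationError(
            f"n_contigs={n_contigs} cannot host {n_genes} genes "
            f"plus {n_marker_contigs} marker contigs"
        )
    if spec.contig_len < MAX_CDS_NT + 2 * spec.margin:
        raise SimulationError(
            f"contig_len={spec.contig_len} too short for a "
            f"{MAX_CDS_NT} nt gene with {spec.margin} nt margins"
        )

    contigs: dict[str, str] = {}
    truth = TruthTable()
    gene_no = 0

    def plant_full(category: str, contig_id: str) -> str:
        nonlocal gene_no
        gene_no += 1
        qname = query_names[int(rng.integers(len(query_names)))]
        prot = diverge_protein(queries[qname], spec.divergence, rng)
        orf = make_orf(prot, rng)
        disruptions = []
        if category == "PSEUDO":
            orf, disruptions = mutate_to_pseudogene(
                orf, int(rng.integers(1, 3)), rng
            )
        strand = "+" if rng.random() < 0.5 else "-"
        insert = orf if strand == "+" else revcomp(orf)
        start = int(
            rng.integers(spec.margin, spec.contig_len - spec.margin - len(insert))
        )
        left = _random_dna(rng, start, spec.gc)
        right = _random_dna(rng, spec.contig_len - start - len(insert), spec.gc)
        contigs[contig_id] = left + insert + right
        truth.records.append(
            TruthRecord(
                gene_id=f"plant{gene_no}",
                contig_id=contig_id,
                strand=strand,
                start=start,
                end=start + len(insert),
                category=category,
                family=spec.family,
                disruptions=disruptions,
            )
        )
        return contig_id

    def plant_partial(contig_id: str) -> None:
        nonlocal gene_no
        gene_no += 1
        qname = query_names[int(rng.integers(len(query_names)))]
        prot = diverge_protein(queries[qname], spec.divergence, rng)
        orf = make_orf(prot, rng)
        keep = int(len(orf) * rng.uniform(0.45, 0.7))
        missing_stop = rng.random() < 0.5
        strand = "+" if rng.random() < 0.5 else "-"
        if missing_stop:
            piece = orf[:keep]  # head of the gene; tail lost past the edge
        else:
            piece = orf[-keep:]  # tail; start codon lost past the edge
        if strand == "-":
            piece = revcomp(piece)
            at_start = missing_stop  # revcomp flips which edge truncates
        else:
            at_start = not missing_stop
        filler = _random_dna(rng, spec.contig_len - keep, spec.gc)
        if at_start:
            contigs[contig_id] = piece + filler
            start, end = 0, keep
        else:
            contigs[contig_id] = filler + piece
            start, end = spec.contig_len - keep, spec.contig_len
        truth.records.append(
            TruthRecord(
                gene_id=f"plant{gene_no}",
                contig_id=contig_id,
                strand=strand,
                start=start,
                end=end,
                category="PARTIAL",
                family=spec.family,
            )
        )

    idx = 0
    for _ in range(spec.n_intact):
        idx += 1
        plant_full("INTACT", f"contig{idx}")
    for _ in range(spec.n_pseudo):
        idx += 1
        plant_full("PSEUDO", f"contig{idx}")
    for _ in range(spec.n_partial):
        idx += 1
        plant_partial(f"contig{idx}")

    if spec.with_markers:
        if spec.n_intact > 0:
            # markers flanking the first intact plant: the "present" scenario
            rec = truth.records[0]
            truth.markers.append(
                MarkerPlacement(
                    "NOL9", rec.contig_id, max(0, rec.start - 550), rec.start - 250
                )
            )
            truth.markers.append(
                MarkerPlacement(
                    "ZBTB48",
                    rec.contig_id,
                    rec.end + 250,
                    min(spec.contig_len, rec.end + 550),
                )
            )
        # contig with a marker pair but no target between them: true absence
        idx += 1
        cid = f"contig{idx}"
        contigs[cid] = _random_dna(rng, spec.contig_len, spec.gc)
        truth.markers.append(MarkerPlacement("MIB2", cid, 100, 400))
        truth.markers.append(MarkerPlacement("GOLIM4", cid, 2100, 2400))

    while idx < n_contigs:
        idx += 1
        contigs[f"contig{idx}"] = _random_dna(rng, spec.contig_len, spec.gc)

    return GenomeAssembly(contigs=contigs), truth


# ---------------------------------------------------------------------------
# gene-family birth--death simulation
# ---------------------------------------------------------------------------


@dataclass
class _GNode:
    name: str | None = None
    children: list = field(default_factory=list)
    alive: bool = True  # for tips during simulation


@dataclass
class TruthEvent:
    branch: str  # canonical branch key: sorted leaf names under the child node
    kind: str  # DUPLICATION | LOSS
    observable: bool = True
    node: object = None


@dataclass
class FamilyHistory:
    species_tree: str  # newick
    gene_trees: list  # newick strings, one per surviving root lineage
    events: list  # TruthEvent
    terminal_counts: dict  # species -> surviving gene count
    extinct: bool = False


def branch_key(leaf_names) -> str:
    return ",".join(sorted(leaf_names))


def _parse_species_newick(newick: str):
    """Minimal rooted-tree parse into _GNode (names on leaves only needed)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")

    def conv(nd):
        g = _GNode(name=nd.taxon.label if nd.taxon else nd.label)
        g.children = [conv(c) for c in nd.child_nodes()]
        return g

    return conv(tree.seed_node)


def _leaves(node: _GNode):
    if not node.children:
        return [node]
    out = []
    for c in node.children:
        out.extend(_leaves(c))
    return out


def simulate_family_evolution(
    species_tree: str,
    birth_rate: float,
    death_rate: float,
    root_count: int = 1,
    seed: int = 0,
) -> FamilyHistory:
    """Evolve a gene family along a species tree by per-branch birth--death.

    Each branch is one unit of time; each extant gene lineage independently
    duplicates at ``birth_rate`` and dies at ``death_rate`` (events/branch,
    Poisson process, uniform placement).  Duplications whose descendants do
    not all survive to the tips are flagged unobservable in the truth log.
    """
    if birth_rate < 0 or death_rate < 0:
        raise ValueError("rates must be >= 0")
    if root_count < 1:
        raise ValueError("root_count must be >= 1")
    rng = np.random.default_rng(seed)
    sp_root = _parse_species_newick(species_tree)
    if any(len(n.children) not in (0, 2) for n in _walk(sp_root)):
        raise ValueError("species tree must be binary")

    events: list[TruthEvent] = []
    terminal: dict[str, list] = {leaf.name: [] for leaf in _leaves(sp_root)}

    def evolve_branch(tips: list[_GNode], key: str) -> list[_GNode]:
        """Birth-death on one branch (unit time); returns surviving tips."""
        live = list(tips)
        t = 0.0
        while live:
            total = len(live) * (birth_rate + death_rate)
            if total == 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= 1.0:
                break
            i = int(rng.integers(len(live)))
            node = live[i]
            if rng.random() < birth_rate / (birth_rate + death_rate):
                a, b = _GNode(), _GNode()
                node.children = [a, b]
                live[i] = a
                live.append(b)
                events.append(TruthEvent(key, "DUPLICATION", node=node))
            else:
                node.alive = False
                live.pop(i)
                events.append(TruthEvent(key, "LOSS", node=node))
        return live

    def descend(sp_node: _GNode, tips: list[_GNode]) -> None:
        if not sp_node.children:
            for j, tip in enumerate(tips):
                tip.name = f"{sp_node.name}_g{j + 1}"
                terminal[sp_node.name].append(tip)
            return
        for child in sp_node.children:
            key = branch_key(l.name for l in _leaves(child))
            entering = []
            for tip in tips:
                cont = _GNode()
                tip.children.append(cont)
                entering.append(cont)
            descend(child, evolve_branch(entering, key))

    roots = [_GNode() for _ in range(root_count)]
    root_branch = branch_key(l.name for l in _leaves(sp_root))
    for r in roots:
        descend(sp_root, [r])

    # prune extinct lineages, mark observability, emit newick per root
    gene_trees = []
    for r in roots:
        pruned = _prune(r)
        if pruned is not None:
            gene_trees.append(_to_newick(pruned) + ";")
    for ev in events:
        if ev.kind == "DUPLICATION":
            ev.observable = all(
                _has_survivor(c) for c in ev.node.children
            ) and len(ev.node.children) == 2
        ev.node = None  # drop internal references
    counts = {sp: len(tips) for sp, tips in terminal.items()}
    return FamilyHistory(
        species_tree=species_tree,
        gene_trees=gene_trees,
        events=events,
        terminal_counts=counts,
        extinct=not gene_trees,
    )


def _walk(node: _GNode):
    yield node
    for c in node.children:
        yield from _walk(c)


def _has_survivor(node: _GNode) -> bool:
    if not node.children:
        return node.alive and node.name is not None
    return any(_has_survivor(c) for c in node.children)


def _prune(node: _GNode):
    """Drop dead tips and suppress unifurcations; None if nothing survives."""
    if not node.children:
        return node if (node.alive and node.name is not None) else None
    kept = [p for p in (_prune(c) for c in node.children) if p is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


def _to_newick(node: _GNode) -> str:
    if not node.children:
        return node.name
    return "(" + ",".join(_to_newick(c) for c in node.children) + ")"


# ---------------------------------------------------------------------------
# codon-alignment simulation
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    names: list
    seqs: list  # equal-length nucleotide strings, length % 3 == 0

    def to_fasta(self) -> str:
        return "".join(f">{n}\n{s}\n" for n, s in zip(self.names, self.seqs))

    def __len__(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0


_NEIGHBORS: dict[str, list] = {}
for _c in SENSE_CODONS:
    lst = []
    for _pos in range(3):
        for _b in "ACGT":
            if _b == _c[_pos]:
                continue
            _n = _c[:_pos] + _b + _c[_pos + 1 :]
            if CODON_TO_AA[_n] == "*":
                continue
            lst.append(
                (
                    _n,
                    is_transition(_c[_pos], _b),
                    CODON_TO_AA[_n] == CODON_TO_AA[_c],
                )
            )
    _NEIGHBORS[_c] = lst


def _site_rates(omega: float, kappa: float):
    """(rates dict, normaliser) for one site: rates are per-codon lists
    aligned with _NEIGHBORS; normaliser makes branch lengths expected
    substitutions per codon site under uniform codon frequencies."""
    rates = {}
    total = 0.0
    for c in SENSE_CODONS:
        rl = []
        for _, ti, syn in _NEIGHBORS[c]:
            r = (kappa if ti else 1.0) * (1.0 if syn else omega)
            rl.append(r)
        rates[c] = rl
        total += sum(rl)
    return rates, total / len(SENSE_CODONS)


def simulate_codon_alignment(
    tree: str,
    omega,
    kappa: float = 2.0,
    n_codons: int = 300,
    seed: int = 0,
) -> CodonAlignment:
    """Evolve codons along a tree under a site-wise dN/dS model.

    ``omega`` is a scalar or a per-site sequence; nonsynonymous rates are
    scaled by the site's omega, transitions by kappa.  No stop codons are
    ever introduced; the alignment is gap-free.  Branch lengths are read
    from the newick; a zero-length tree yields identical rows.
    """
    import dendropy

    rng = np.random.default_rng(seed)
    dtree = dendropy.Tree.get(data=tree, schema="newick")
    omegas = np.broadcast_to(np.asarray(omega, dtype=float), (n_codons,))
    if np.any(omegas <= 0):
        raise ValueError("omega values must be > 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")

    site_models = {}
    for w in np.unique(omegas):
        site_models[float(w)] = _site_rates(float(w), kappa)

    root_seq = [
        SENSE_CODONS[int(i)]
        for i in rng.integers(0, len(SENSE_CODONS), n_codons)
    ]

    names, seqs = [], []

    def evolve(codon: str, w: float, t: float) -> str:
        rates, norm = site_models[w]
        elapsed = 0.0
        while True:
            rl = rates[codon]
            total = sum(rl) / norm
            elapsed += rng.exponential(1.0 / total)
            if elapsed >= t:
                return codon
            u = rng.random() * sum(rl)
            acc = 0.0
            for (nb, _, _), r in zip(_NEIGHBORS[codon], rl):
                acc += r
                if u <= acc:
                    codon = nb
                    break

    def descend(node, seq):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            if t > 0:
                new = [
                    evolve(c, float(w), t) for c, w in zip(seq, omegas)
                ]
            else:
                new = list(seq)
            if child.is_leaf():
                names.append(child.taxon.label)
                seqs.append("".join(new))
            else:
                descend(child, new)

    if dtree.seed_node.is_leaf():  # degenerate single-taxon tree
        names.append(dtree.seed_node.taxon.label)
        seqs.append("".join(root_seq))
    else:
        descend(dtree.seed_node, root_seq)
    return CodonAlignment(names=names, seqs=seqs)


def write_event_log_tsv(history: FamilyHistory) -> str:
    lines = ["branch\tkind\tobservable"]
    for ev in history.events:
        lines.append(f"{ev.branch}\t{ev.kind}\t{int(ev.observable)}")
    return "\n".join(lines) + "\n"
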