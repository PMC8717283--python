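"""Pipeline orchestration and repertoire summaries.

`run_pipeline` wires the stages together (simulate/load -> search ->
annotate -> synteny -> reconcile -> selection -> taste -> report), writes
per-stage outputs to a directory and is byte-deterministic for a fixed
configuration and seed.  `summarize_repertoire` produces the per-species
intact/partial/pseudo tallies, and `score_against_truth` measures mining
performance against a synthetic TruthTable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate, search, selection, simdata, synteny, taste
from . import reconcile as rc

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "search",
    "annotate",
    "synteny",
    "reconcile",
    "selection",
    "taste",
    "report",
)


@dataclass
class RepertoireSummary:
    species: str
    intact: int
    partial: int
    pseudo: int
    short: int = 0

    @property
    def total(self) -> int:
        return self.intact + self.partial + self.pseudo

    @property
    def pseudo_percent(self) -> float:
        return round(100.0 * self.pseudo / self.total, 1) if self.total else 0.0


def summarize_repertoire(models_by_species: dict) -> list[RepertoireSummary]:
    """Per-species intact/partial/pseudo counts (SHORT reported separately).

    Accepts GeneModel lists or plain category-string lists per species.
    """
    out = []
    for species, models in models_by_species.items():
        cats = [getattr(m, "category", m) for m in models]
        s = RepertoireSummary(
            species=species,
            intact=cats.count("INTACT"),
            partial=cats.count("PARTIAL"),
            pseudo=cats.count("PSEUDO"),
            short=cats.count("SHORT"),
        )
        assert s.total == s.intact + s.partial + s.pseudo
        out.append(s)
    return out


def summary_to_tsv(summaries: list[RepertoireSummary]) -> str:
    lines = ["species\tintact\tpartial\tpseudo\ttotal\tpseudo_percent\tshort"]
    for s in summaries:
        lines.append(
            f"{s.species}\t{s.intact}\t{s.partial}\t{s.pseudo}\t{s.total}\t"
            f"{s.pseudo_percent:.1f}\t{s.short}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# truth-table scoring (synthetic benchmarks)
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    n_truth: int
    n_predicted: int
    recall: float  # truth genes overlapped by a prediction
    precision: float  # predictions overlapping a truth gene
    category_accuracy: float  # truth genes whose best prediction matches


def _overlaps(rec, model) -> bool:
    return (
        rec.contig_id == model.contig_id
        and rec.start < model.coding_end
        and model.coding_start < rec.end
    )


def score_against_truth(
    models: list, truth: simdata.TruthTable
) -> RecoveryMetrics:
    n_truth = len(truth.records)
    n_pred = len(models)
    found = 0
    cat_ok = 0
    for rec in truth.records:
        ms = [m for m in models if _overlaps(rec, m)]
        if not ms:
            continue
        found += 1
        best = max(ms, key=lambda m: m.score)
        if best.category == rec.category:
            cat_ok += 1
    true_pred = sum(
        1 for m in models if any(_overlaps(r, m) for r in truth.records)
    )
    return RecoveryMetrics(
        n_truth=n_truth,
        n_predicted=n_pred,
        recall=found / n_truth if n_truth else 1.0,
        precision=true_pred / n_pred if n_pred else 1.0,
        category_accuracy=cat_ok / n_truth if n_truth else 1.0,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 7,
    "species": "Synthetica exempli",
    "family": "Tas2r",
    "genome": {
        "simulate": {
            "n_intact": 20,
            "n_partial": 5,
            "n_pseudo": 5,
            "divergence": 0.1,
        }
    },
    "queries": "simulate",
    "search": {},
    "stages": list(ALL_STAGES),
    "reconcile": {
        "species_tree": "(((A,B),C),(D,E));",
        "n_families": 10,
        "birth_rate": 0.3,
        "death_rate": 0.0,
    },
    "selection": {
        "tree": "(((a:0.15,b:0.15):0.1,(c:0.15,d:0.15):0.1):0.05,"
                "((e:0.15,f:0.15):0.1,(g:0.15,h:0.15):0.1):0.05,i:0.3);",
        "omega": 0.2,
        "n_codons": 300,
    },
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "tastemine_out"):
    """Execute the configured stages; returns a dict of in-memory results.

    Stage outputs (TSV/BED/GFF3/FASTA/JSON) are written under ``out_dir``.
    Re-running with an identical config is byte-identical.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    stages = cfg.get("stages") or list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError("config", f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    family = cfg.get("family", "Tas2r")
    results: dict = {"config": cfg}

    genome = truth = queries = None
    if "simulate" in stages or "search" in stages:
        gcfg = cfg.get("genome")
        if not gcfg:
            raise PipelineError("simulate", "config field 'genome' is missing")
        if isinstance(gcfg, dict) and "simulate" in gcfg:
            spec = simdata.SimSpec(seed=seed, family=family, **gcfg["simulate"])
            genome, truth = simdata.simulate_genome(spec)
            queries = simdata.simulate_queries(spec)
            if "simulate" in stages:
                (out / "genome.fa").write_text(genome.to_fasta())
                (out / "truth.gff3").write_text(truth.to_gff3())
                _write_fasta(out / "queries.faa", queries)
            results.update(genome=genome, truth=truth, queries=queries)
        else:
            genome = simdata.GenomeAssembly(contigs=_read_fasta(gcfg["fasta"]))
            results["genome"] = genome
    qcfg = cfg.get("queries")
    if queries is None and "search" in stages:
        if not qcfg or qcfg == "simulate":
            raise PipelineError(
                "search", "config field 'queries' must name a FASTA file"
            )
        queries = _read_fasta(qcfg)
        results["queries"] = queries

    params = search.SearchParams(**cfg.get("search", {}))
    hits = loci = models = None
    if "search" in stages:
        if not queries:
            raise PipelineError("search", "no queries available")
        hits = search.search_genome(queries, genome, params)
        kept = search.filter_hits(hits, params)
        merged = search.merge_hits(kept, params)
        loci = [
            search.extend_locus(l, params, len(genome.contigs[l.contig_id]))
            for l in merged
        ]
        (out / "hits.tsv").write_text(search.hits_to_tsv(hits))
        (out / "loci.bed").write_text(search.loci_to_bed(loci))
        results.update(hits=hits, loci=loci)

    if "annotate" in stages:
        if loci is None:
            raise PipelineError("annotate", "search stage did not run")
        models = annotate.annotate_loci(genome, loci, queries, family=family)
        models = annotate.assign_gene_names(
            models, cfg.get("species", "Synthetica exempli"), family
        )
        (out / "models.tsv").write_text(annotate.models_to_tsv(models))
        (out / "models.gff3").write_text(annotate.models_to_gff3(models))
        (out / "proteins.faa").write_text(
            annotate.models_to_protein_fasta(models)
        )
        results["models"] = models

    if "synteny" in stages and truth is not None and models is not None:
        markers = [
            synteny.MarkerAnnotation(m.marker, m.contig_id, m.start, m.end)
            for m in truth.markers
        ]
        calls = {}
        sp = cfg.get("species", "Synthetica exempli")
        # the planted "present" pair flanks a real gene; the second marker
        # pair brackets an empty interval: expected ABSENT
        for rule in (
            synteny.MarkerRule(family, "NOL9", "ZBTB48"),
            synteny.MarkerRule(family + "-like", "MIB2", "GOLIM4"),
        ):
            pair_contigs = {
                m.contig_id
                for m in markers
                if m.marker in (rule.upstream, rule.downstream)
            }
            local_models = [m for m in models if m.contig_id in pair_contigs]
            local_hits = [
                h for h in (hits or []) if h.contig_id in pair_contigs
            ]
            calls[(sp, rule.family)] = synteny.call_gene_status(
                local_models, local_hits, markers, rule
            )
        (out / "synteny.tsv").write_text(synteny.status_table_tsv(calls))
        results["synteny"] = calls

    if "reconcile" in stages:
        rcfg = cfg.get("reconcile", {})
        sp_tree = rcfg.get("species_tree")
        histories = []
        recons = []
        counts: dict[str, int] = {}
        for i in range(int(rcfg.get("n_families", 10))):
            h = simdata.simulate_family_evolution(
                sp_tree,
                rcfg.get("birth_rate", 0.3),
                rcfg.get("death_rate", 0.0),
                root_count=1,
                seed=(seed * 1009 + i) % (2**31),
            )
            if h.extinct:
                continue
            histories.append(h)
            for g in h.gene_trees:
                recons.append(rc.lca_reconcile(g, sp_tree))
            for sp_name, n in h.terminal_counts.items():
                counts[sp_name] = counts.get(sp_name, 0) + n
        traj = rc.ancestral_trajectory(recons, sp_tree, observed_counts=counts)
        (out / "trajectory.tsv").write_text(rc.trajectory_to_tsv(traj))
        results.update(trajectory=traj, histories=histories)

    if "selection" in stages:
        scfg = cfg.get("selection", {})
        aln = simdata.simulate_codon_alignment(
            scfg["tree"],
            scfg.get("omega", 0.2),
            kappa=scfg.get("kappa", 2.0),
            n_codons=int(scfg.get("n_codons", 300)),
            seed=seed,
        )
        mean_omega, n_def, n_undef = selection.mean_family_omega(aln)
        scan = selection.site_selection_scan(aln)
        (out / "alignment.fa").write_text(aln.to_fasta())
        (out / "dnds.tsv").write_text(
            selection.dnds_table(aln).to_csv(sep="\t", index=False)
        )
        (out / "sites.tsv").write_text(selection.site_table_tsv(scan))
        results.update(mean_omega=mean_omega, site_scan=scan)

    if "taste" in stages:
        profiles = taste.reference_profiles()
        cohort = taste.summarize_cohort(profiles)
        (out / "taste_profiles.tsv").write_text(
            taste.profiles_to_tsv(profiles)
        )
        results.update(taste_profiles=profiles, cohort=cohort)

    if "report" in stages and models is not None:
        sp = cfg.get("species", "Synthetica exempli")
        summaries = summarize_repertoire({sp: models})
        (out / "repertoire.tsv").write_text(summary_to_tsv(summaries))
        results["repertoire"] = summaries
        if truth is not None:
            metrics = score_against_truth(models, truth)
            (out / "recovery.json").write_text(
                json.dumps(dataclass_dict(metrics), indent=2) + "\n"
            )
            results["recovery"] = metrics
            logger.info(
                "recovery: recall=%.3f precision=%.3f category=%.3f",
                metrics.recall, metrics.precision, metrics.category_accuracy,
            )

    return results


def dataclass_dict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def _write_fasta(path: Path, records: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def _read_fasta(path) -> dict:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }
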