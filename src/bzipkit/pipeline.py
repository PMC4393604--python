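"""End-to-end orchestration: validated run configuration + run manifest.

Stages run in dependency order (domain scan first, then dimerization and
intron patterns, with CpG/duplication, phylogeny and expression as inputs
allow). Partial inputs run partial pipelines; a stage failure aborts its
dependents but leaves independent stages running, and the manifest is
written even on failure with the failing stage recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import dimerization, domain_scan, expression, introns, landscape, phylogeny
from . import io as bio

log = logging.getLogger(__name__)

KNOWN_KEYS = {
    "proteins", "gene_models", "genome", "alignment", "ct_table",
    "condition_meta", "reference_gene", "calibrator_condition",
    "window_size", "cpg_quantile", "identity_min", "max_block",
    "replicates", "seed", "k", "distance", "linkage", "out_dir",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    proteins: str | None = None
    gene_models: str | None = None
    genome: str | None = None
    alignment: str | None = None
    ct_table: str | None = None
    condition_meta: str | None = None
    reference_gene: str | None = None
    calibrator_condition: str | None = None
    window_size: int = 100_000
    cpg_quantile: float = 0.75
    identity_min: float = 0.7
    max_block: int = 100_000
    replicates: int = 1000
    seed: int = 0
    k: int = 4
    distance: str = "correlation"
    linkage: str = "average"
    out_dir: str = "bzipkit_out"

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("proteins", "gene_models", "genome", "alignment", "ct_table",
                     "condition_meta"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{attr}: file not found: {path}")
        if self.ct_table and not (self.reference_gene and self.calibrator_condition):
            raise ConfigError(
                "ct_table requires reference_gene and calibrator_condition"
            )
        if self.window_size < 1 or self.replicates < 1 or self.k < 1:
            raise ConfigError("window_size, replicates and k must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    started: float = field(default_factory=time.time)
    finished: float | None = None
    stages: dict = field(default_factory=dict)  # stage -> status
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    failure_stage: str | None = None

    def write(self, out_dir: Path) -> None:
        self.finished = time.time()
        for f in sorted(out_dir.glob("*.tsv")) + sorted(out_dir.glob("*.nwk")):
            self.outputs[f.name] = _sha256(f)
        (out_dir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n"
        )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage the configured inputs allow; write reports + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))

    annotations: dict[str, domain_scan.BzipDomainAnnotation] = {}
    tables: dict[str, domain_scan.HeptadTable] = {}
    proteins: list[bio.ProteinRecord] = []
    pattern_by_gene: dict[str, str] = {}

    def stage(name: str, fn, *deps_ok: bool) -> bool:
        if not all(deps_ok):
            manifest.stages[name] = "skipped (failed dependency)"
            return False
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - recorded in manifest
            log.exception("stage %s failed", name)
            manifest.stages[name] = f"failed: {exc}"
            if manifest.failure_stage is None:
                manifest.failure_stage = name
            return False
        manifest.stages[name] = "ok"
        return True

    scan_ok = dimer_ok = introns_ok = False

    if config.proteins:
        def _scan():
            nonlocal proteins
            proteins = bio.read_fasta(config.proteins)
            scanned = []
            for p in proteins:
                ann, table = domain_scan.scan_protein(p)
                annotations[p.id] = ann
                if table is not None:
                    tables[p.id] = table
                scanned.append((ann, table))
            domain_scan.scan_report(scanned).to_csv(
                out / "domain_scan.tsv", sep="\t", index=False
            )
        scan_ok = stage("domain_scan", _scan)

        def _dimer():
            ht = list(tables.values())
            if not ht:
                raise ValueError("no proteins with a zipper to profile")
            dimerization.composition_report(ht).to_csv(
                out / "position_composition.tsv", sep="\t", index=False
            )
            dimerization.asn_report(ht).to_csv(
                out / "asn_by_heptad.tsv", sep="\t", index=False
            )
            all_calls = [dimerization.call_ge_pairs(t) for t in ht]
            dimerization.ge_report(all_calls).to_csv(
                out / "ge_histogram.tsv", sep="\t", index=False
            )
            profiles = [dimerization.profile_protein(t) for t in ht]
            dimerization.subfamily_report(profiles).to_csv(
                out / "subfamilies.tsv", sep="\t", index=False
            )
        dimer_ok = stage("zipper_dimerization", _dimer, scan_ok)
    else:
        manifest.stages["domain_scan"] = "skipped (no proteins input)"
        log.info("no protein input: domain and dimerization stages skipped")

    gene_positions: dict[str, tuple[str, int, int]] = {}
    protein_to_gene: dict[str, str] = {}
    if config.gene_models:
        def _introns():
            models = bio.read_gene_models(config.gene_models)
            calls = []
            for m in models:
                gene_positions[m.gene_id] = (m.chromosome, m.span.start, m.span.end)
                protein_to_gene[m.protein_id] = m.gene_id
                recs = introns.extract_introns(m)
                ann = annotations.get(m.protein_id)
                call = introns.classify_pattern(m.gene_id, recs, ann)
                pattern_by_gene[m.gene_id] = call.pattern
                calls.append(call)
            introns.pattern_report(calls).to_csv(
                out / "intron_patterns.tsv", sep="\t", index=False
            )
            census = introns.pattern_census(calls)
            pd.DataFrame([census["patterns"]]).assign(
                genes_with_introns=census["genes_with_introns"],
                intronless_genes=census["intronless_genes"],
                genes_with_1_2_region_introns=census["genes_with_1_2_region_introns"],
            ).to_csv(out / "pattern_census.tsv", sep="\t", index=False)
        introns_ok = stage("intron_patterns", _introns, scan_ok or not config.proteins)
    else:
        manifest.stages["intron_patterns"] = "skipped (no gene models input)"
        log.info("no gene-model input: intron stage skipped")

    if config.genome:
        def _cpg():
            genome = bio.read_genome_fasta(config.genome)
            profiles = [
                landscape.cpg_windows(seq, chrom, config.window_size)
                for chrom, seq in genome.items()
            ]
            landscape.classify_windows(profiles, config.cpg_quantile)
            landscape.cpg_report(profiles).to_csv(
                out / "cpg_windows.tsv", sep="\t", index=False
            )
            if gene_positions:
                landscape.assign_genes(profiles, gene_positions).to_csv(
                    out / "gene_cpg_assignment.tsv", sep="\t", index=False
                )
        stage("cpg_landscape", _cpg)
    else:
        manifest.stages["cpg_landscape"] = "skipped (no genome input)"

    if config.proteins and config.gene_models:
        def _dup():
            pairs = landscape.find_duplicate_pairs(
                proteins, annotations, gene_positions,
                identity_min=config.identity_min, max_block=config.max_block,
                protein_to_gene=protein_to_gene,
            )
            landscape.duplicate_report(pairs).to_csv(
                out / "duplicate_pairs.tsv", sep="\t", index=False
            )
        stage("duplications", _dup, scan_ok, introns_ok)

    if config.alignment:
        def _tree():
            ids, rows = bio.read_alignment_fasta(config.alignment)
            aln = phylogeny.Alignment(ids, rows)
            dist = phylogeny.p_distance(aln)
            phylogeny.distance_report(dist).to_csv(out / "p_distance.tsv", sep="\t")
            tree, used = phylogeny.bootstrap(
                aln, replicates=config.replicates, seed=config.seed
            )
            (out / "tree.nwk").write_text(bio.write_newick(tree) + "\n")
            log.info("bootstrap used %d/%d replicates", used, config.replicates)
        stage("phylogeny", _tree)
    else:
        manifest.stages["phylogeny"] = "skipped (no alignment input)"

    if config.ct_table:
        def _expr():
            ct = bio.read_ct_table(
                config.ct_table, config.reference_gene, config.calibrator_condition
            )
            meta = (
                pd.read_csv(config.condition_meta, sep="\t")
                if config.condition_meta else None
            )
            matrix = expression.delta_delta_ct(ct, meta)
            matrix.minus_ddct.to_csv(out / "minus_ddct.tsv", sep="\t")
            calls = expression.de_calls(matrix)
            calls.to_csv(out / "de_calls.tsv", sep="\t", index=False)
            clusters = expression.cluster_expression(
                matrix, k=config.k, distance=config.distance,
                linkage_method=config.linkage,
            )
            clusters.labels.rename_axis("gene_id").reset_index().to_csv(
                out / "expression_clusters.tsv", sep="\t", index=False
            )
            if meta is not None:
                expression.de_summary_by_group(calls, meta).to_csv(
                    out / "de_by_group.tsv", sep="\t"
                )
            if pattern_by_gene:
                tab = expression.pattern_enrichment(clusters, pattern_by_gene)
                if not tab.empty:
                    tab.to_csv(out / "pattern_enrichment.tsv", sep="\t")
        stage("expression", _expr)
    else:
        manifest.stages["expression"] = "skipped (no Ct table input)"

    manifest.write(out)
    return manifest
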