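"""Seeded synthetic-data generators with machine-readable ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes, so the whole pipeline is testable with no downloads:

* :func:`gen_protein_cohort` — proteins built as random N-terminus +
  canonical basic motif (``N-x7-R/K``) + x9 hinge + leucine zipper of 4-9
  heptads with position-specific residue probabilities (Asn at *a*, Leu at
  *d*, planted g<->e pair classes) + a hydrophobic-free C-terminal tail.
* :func:`gen_gene_models` — back-translates each protein to a CDS, plants
  introns producing an exact requested (sub-region, phase) pattern a-h, and
  embeds the genes on both strands of a genome whose CpG density follows a
  piecewise profile (first-order Markov chain with per-block CG transition
  mass).
* :func:`gen_ct_table` — replicate-level qPCR Ct values for 14 stress
  conditions in 3 treatment groups with planted cluster structure.

Construction guarantees that make recovery exact in the absence of noise:
Asn occurs only at zipper *a* slots, so the planted basic motif is the
unique ``N-x7-R/K`` match; the basic x7 is all R/K, so its 18-residue
window out-scores any zipper window on R+K count; the register-anchor
heptad always carries Leu at *d* (``leu_d_prob`` governs later heptads)
and no L/I/V/M occurs upstream of it in the zipper; the tail carries no
hydrophobic residue, so the two-degenerate-heptad stop rule fires exactly
at the planted zipper end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CtTable, GeneModel, ProteinRecord, Span

# residue pools (see module docstring for why L/I/V/M and N are excluded
# where they are)
NTERM_POOL = list("ASTGPEDQVRK")
HINGE_POOL = list("ASTQGPE")
BCF_POOL = list("ASTQGYHP")
A_ALT_POOL = list("QSTARKED")
D_ALT_POOL = list("IVM")
NEUTRAL_POOL = list("QSTA")
TAIL_POOL = list("STQGEPD")

ACIDS = list("DE")
BASES = list("RK")

PATTERNS = ("a", "b", "c", "d", "e", "f", "g", "h")

#: Most-frequent-codon back-translation table (purely synthetic convention).
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _default_asn_a_prob() -> dict[int, float]:
    # Solved once so the pooled Asn-at-a fraction is 0.23 with a 0.55
    # heptad-2+5 share under the uniform 4-9 heptad-count distribution.
    return {i: (0.448 if i in (2, 5) else 0.144) for i in range(1, 10)}


def _default_ge_probs() -> dict[int, tuple[float, float, float]]:
    # (attractive, repulsive, incomplete) per pair index; remainder "none".
    # Shape mirrors the observed cohort trend: attractive pairs peak at the
    # first heptad pair, dip, rise again around the fifth, and vanish by the
    # eighth where only repulsive pairs remain.
    return {
        1: (0.45, 0.10, 0.20),
        2: (0.20, 0.10, 0.20),
        3: (0.15, 0.10, 0.20),
        4: (0.12, 0.10, 0.20),
        5: (0.30, 0.10, 0.20),
        6: (0.18, 0.10, 0.20),
        7: (0.12, 0.10, 0.20),
        8: (0.00, 0.15, 0.10),
    }


def _default_pattern_mix() -> dict[str, float]:
    # Qualitative census of the study cohort: a, b, e, h prevalent;
    # c, d, f, g uncommon; most genes region-intronless.
    return {"a": 0.05, "b": 0.04, "c": 0.02, "d": 0.02,
            "e": 0.04, "f": 0.01, "g": 0.01, "h": 0.81}


@dataclass
class GenomeSpec:
    """Piecewise CpG-density genome: per-chromosome (length, cg_prob) blocks.

    ``cg_prob`` is the C->G transition mass of the first-order Markov chain;
    the expected CpG density of a block is about 0.25 * cg_prob.
    """

    chromosomes: dict[str, list[tuple[int, float]]] = field(
        default_factory=lambda: {
            "chr1": [(100_000, 0.04), (100_000, 0.04), (100_000, 0.32),
                     (100_000, 0.04), (100_000, 0.04), (100_000, 0.04)],
            "chr2": [(100_000, 0.04), (100_000, 0.32), (100_000, 0.04),
                     (100_000, 0.04), (100_000, 0.32), (100_000, 0.04)],
        }
    )
    window_size: int = 100_000

    def high_blocks(self, threshold: float = 0.1) -> list[tuple[str, int]]:
        """(chromosome, 1-based block index) of planted high-CpG blocks."""
        out = []
        for chrom, blocks in self.chromosomes.items():
            for i, (_, p) in enumerate(blocks):
                if p > threshold:
                    out.append((chrom, i + 1))
        return out


@dataclass
class ExpressionDesign:
    """Planted cluster structure for the qPCR stress panel."""

    n_genes: int = 96
    k: int = 4
    separation: float = 2.0  # cycles between opposite-sign cluster means
    noise_sd: float = 0.5  # replicate Ct noise, cycles
    replicates: int = 3
    reference_gene_id: str = "REF"
    calibrator_condition_id: str = "control"
    conditions: dict[str, str] = field(
        default_factory=lambda: {
            "cold": "environmental", "heat": "environmental",
            "H2O2": "environmental", "PEG": "environmental",
            "NaCl": "environmental",
            "Cu": "heavy_metal", "Zn": "heavy_metal", "Mn": "heavy_metal",
            "Cd": "heavy_metal", "Pb": "heavy_metal",
            "SA": "phytohormone", "6-BA": "phytohormone",
            "ABA": "phytohormone", "MeJA": "phytohormone",
        }
    )


@dataclass
class CohortSpec:
    """Full study-conditions description for all generators."""

    n_proteins: int = 96
    heptad_counts: dict[int, float] = field(
        default_factory=lambda: {n: 1 / 6 for n in range(4, 10)}
    )
    asn_a_prob: dict[int, float] = field(default_factory=_default_asn_a_prob)
    # per-slot Leu probability for heptads after the anchor heptad (whose d
    # is always Leu); 0.622 makes the pooled Leu-at-d fraction 0.68 under
    # the uniform 4-9 heptad-count distribution
    leu_d_prob: float = 0.622
    ge_probs: dict[int, tuple[float, float, float]] = field(
        default_factory=_default_ge_probs
    )
    pattern_mix: dict[str, float] = field(default_factory=_default_pattern_mix)
    extra_intron_prob: float = 0.35  # chance of one intron outside the region
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    expression: ExpressionDesign = field(default_factory=ExpressionDesign)

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if abs(sum(self.heptad_counts.values()) - 1) > 1e-9:
            raise ValueError("heptad-count distribution must sum to 1")
        if any(n < 4 or n > 9 for n in self.heptad_counts):
            raise ValueError("heptad counts must lie in 4..9")
        for i, p in self.asn_a_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"asn_a_prob[{i}]={p} outside [0,1]")
        if not 0 <= self.leu_d_prob <= 1:
            raise ValueError("leu_d_prob outside [0,1]")
        for i, probs in self.ge_probs.items():
            if min(probs) < 0 or sum(probs) > 1 + 1e-9:
                raise ValueError(f"ge_probs[{i}] infeasible: {probs}")
        if abs(sum(self.pattern_mix.values()) - 1) > 1e-9:
            raise ValueError("pattern mix must sum to 1")
        if set(self.pattern_mix) - set(PATTERNS):
            raise ValueError("unknown pattern keys in mix")
        if self.expression.k > self.expression.n_genes:
            raise ValueError("more expression clusters than genes")


@dataclass
class ProteinTruth:
    """Generator ground truth for one protein."""

    protein_id: str
    basic_span: Span
    hinge_span: Span
    zipper_span: Span
    register_anchor: int
    n_heptads: int
    heptads: list[dict[str, str]]
    pair_classes: list[str]  # index i -> class of pair g(i)<->e(i+1)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _choice(rng, pool) -> str:
    return pool[int(rng.integers(0, len(pool)))]


def gen_protein_cohort(
    spec: CohortSpec, seed=0
) -> tuple[list[ProteinRecord], list[ProteinTruth]]:
    """Generate a protein cohort with exact domain-architecture ground truth."""
    spec.validate()
    rng = _rng(seed)
    ns = sorted(spec.heptad_counts)
    probs = np.array([spec.heptad_counts[n] for n in ns])
    records, truths = [], []
    for idx in range(spec.n_proteins):
        pid = f"SYNbZIP{idx + 1:03d}"
        n_heptads = int(rng.choice(ns, p=probs))
        nterm_len = int(rng.integers(5, 21))
        nterm = "".join(_choice(rng, NTERM_POOL) for _ in range(nterm_len))
        basic = "N" + "".join(_choice(rng, BASES) for _ in range(7)) + _choice(rng, BASES)
        hinge_list = [_choice(rng, HINGE_POOL) for _ in range(9)]
        for pos in rng.choice(9, size=2, replace=False):
            hinge_list[int(pos)] = _choice(rng, BASES)
        hinge = "".join(hinge_list)

        # plant g<->e pair classes, then fill the per-heptad slots
        pair_classes = []
        g_res = [None] * (n_heptads + 1)  # 1-based
        e_res = [None] * (n_heptads + 1)
        e_res[1] = _choice(rng, NEUTRAL_POOL)
        g_res[n_heptads] = _choice(rng, NEUTRAL_POOL)
        for i in range(1, n_heptads):
            att, rep, inc = spec.ge_probs.get(i, (0.0, 0.0, 0.0))
            u = rng.random()
            if u < att:
                cls = "attractive"
                pair = (_choice(rng, ACIDS), _choice(rng, BASES))
            elif u < att + rep:
                cls = "repulsive"
                pool = ACIDS if rng.random() < 0.5 else BASES
                pair = (_choice(rng, pool), _choice(rng, pool))
            elif u < att + rep + inc:
                cls = "incomplete"
                pair = (_choice(rng, ACIDS + BASES), _choice(rng, list("QST")))
            else:
                cls = "none"
                pair = (_choice(rng, NEUTRAL_POOL), _choice(rng, NEUTRAL_POOL))
            if cls in ("attractive", "incomplete") and rng.random() < 0.5:
                pair = (pair[1], pair[0])
            g_res[i], e_res[i + 1] = pair
            pair_classes.append(cls)

        heptads = []
        zipper_parts = []
        for i in range(1, n_heptads + 1):
            a = "N" if rng.random() < spec.asn_a_prob.get(i, 0.0) else _choice(rng, A_ALT_POOL)
            if i == 1:
                d = "L"  # register anchor is always a leucine
            else:
                d = "L" if rng.random() < spec.leu_d_prob else _choice(rng, D_ALT_POOL)
            row = {
                "a": a,
                "b": _choice(rng, BCF_POOL),
                "c": _choice(rng, BCF_POOL),
                "d": d,
                "e": e_res[i],
                "f": _choice(rng, BCF_POOL),
                "g": g_res[i],
            }
            heptads.append(row)
            zipper_parts.append("".join(row[p] for p in "abcdefg"))
        zipper = "".join(zipper_parts)
        tail = "".join(_choice(rng, TAIL_POOL) for _ in range(18))
        sequence = nterm + basic + hinge + zipper + tail

        basic_span = Span(nterm_len + 1, nterm_len + 9)
        hinge_span = Span(nterm_len + 10, nterm_len + 18)
        zipper_span = Span(nterm_len + 19, nterm_len + 18 + 7 * n_heptads)
        truths.append(
            ProteinTruth(
                protein_id=pid,
                basic_span=basic_span,
                hinge_span=hinge_span,
                zipper_span=zipper_span,
                register_anchor=nterm_len + 22,
                n_heptads=n_heptads,
                heptads=heptads,
                pair_classes=pair_classes,
            )
        )
        records.append(ProteinRecord(pid, sequence))
    return records, truths


def cohort_truth_table(truths: list[ProteinTruth]) -> pd.DataFrame:
    """Machine-readable ground-truth TSV for a protein cohort."""
    rows = []
    for t in truths:
        rows.append(
            {
                "protein_id": t.protein_id,
                "basic_start": t.basic_span.start,
                "basic_end": t.basic_span.end,
                "hinge_start": t.hinge_span.start,
                "hinge_end": t.hinge_span.end,
                "zipper_start": t.zipper_span.start,
                "zipper_end": t.zipper_span.end,
                "register_anchor": t.register_anchor,
                "n_heptads": t.n_heptads,
                "asn_at_a": "".join(
                    "1" if h["a"] == "N" else "0" for h in t.heptads
                ),
                "leu_at_d": "".join(
                    "1" if h["d"] == "L" else "0" for h in t.heptads
                ),
                "pair_classes": ";".join(t.pair_classes),
            }
        )
    return pd.DataFrame(rows)


def plant_duplicates(
    records: list[ProteinRecord],
    truths: list[ProteinTruth],
    n_pairs: int,
    identity: float = 0.85,
    seed=0,
) -> tuple[list[ProteinRecord], list[ProteinTruth], list[tuple[str, str]]]:
    """Append mutated copies of cohort members as planted duplicate pairs.

    Each copy differs from its original at ``round((1 - identity) * domain
    length)`` positions, substituted only at hinge and b/c/f zipper slots so
    the domain architecture (and its detection) is untouched. Returns the
    extended cohort plus the list of (original, copy) id pairs.
    """
    rng = _rng(seed)
    picks = rng.choice(len(records), size=n_pairs, replace=False)
    new_records = list(records)
    new_truths = list(truths)
    pairs = []
    for orig_idx in picks:
        rec, truth = records[int(orig_idx)], truths[int(orig_idx)]
        domain_len = truth.zipper_span.end - truth.basic_span.start + 1
        n_mut = int(round((1 - identity) * domain_len))
        mutable: list[tuple[int, list[str]]] = []  # (1-based pos, pool)
        for off in range(9):
            pos = truth.hinge_span.start + off
            if rec.sequence[pos - 1] not in BASES:
                mutable.append((pos, HINGE_POOL))
        for i in range(truth.n_heptads):
            base = truth.zipper_span.start + 7 * i
            for slot_off in (1, 2, 5):  # b, c, f
                mutable.append((base + slot_off, BCF_POOL))
        chosen = rng.choice(len(mutable), size=min(n_mut, len(mutable)), replace=False)
        seq = list(rec.sequence)
        for ci in chosen:
            pos, pool = mutable[int(ci)]
            alternatives = [r for r in pool if r != seq[pos - 1]]
            seq[pos - 1] = _choice(rng, alternatives)
        dup_id = rec.id + "dup"
        new_records.append(ProteinRecord(dup_id, "".join(seq)))
        dup_truth = ProteinTruth(
            protein_id=dup_id,
            basic_span=truth.basic_span,
            hinge_span=truth.hinge_span,
            zipper_span=truth.zipper_span,
            register_anchor=truth.register_anchor,
            n_heptads=truth.n_heptads,
            heptads=[dict(h) for h in truth.heptads],
            pair_classes=list(truth.pair_classes),
        )
        new_truths.append(dup_truth)
        pairs.append((rec.id, dup_id))
    return new_records, new_truths, pairs


# ---------------------------------------------------------------------------
# gene models + genome


_PLACEMENTS = {
    # pattern -> list of (subregion, phase) to plant
    "a": [("basic", "P2")],
    "b": [("hinge", "P0")],
    "c": [("basic", "P0")],
    "d": [("hinge", "P2")],
    "e": [("basic", "P2"), ("hinge", "P0")],
    "f": [("basic", "P0"), ("basic", "P0")],
    "g": [("basic", "P0"), ("hinge", "P0")],
    "h": [],
}


def _intron_offsets_for_pattern(
    pattern: str, truth: ProteinTruth, rng
) -> list[int]:
    """Coding offsets planting exactly the requested (subregion, phase) set.

    A P0 junction at offset 3(p-1) is owned by codon p (3' rule); a P2
    junction at 3(p-1)+2 sits inside codon p.
    """
    spans = {"basic": truth.basic_span, "hinge": truth.hinge_span}
    placements = _PLACEMENTS[pattern]
    offsets: list[int] = []
    used_codons: set[int] = set()
    for subregion, phase in placements:
        span = spans[subregion]
        candidates = [p for p in range(span.start, span.end + 1) if p not in used_codons]
        p = int(rng.choice(candidates))
        used_codons.add(p)
        offsets.append(3 * (p - 1) + (2 if phase == "P2" else 0))
    return sorted(offsets)


def _markov_sequence(length: int, cg_prob: float, rng) -> np.ndarray:
    """First-order Markov DNA with CG transition mass ``cg_prob`` (uint8)."""
    A, C, G, T = ord("A"), ord("C"), ord("G"), ord("T")
    others = np.array([A, G, T], dtype=np.uint8)
    out = np.empty(length, dtype=np.uint8)
    u = rng.random(length)
    picks = rng.integers(0, 3, size=length)
    bases = np.array([A, C, G, T], dtype=np.uint8)
    uniform_picks = rng.integers(0, 4, size=length)
    prev_is_c = False
    for i in range(length):
        if prev_is_c:
            if u[i] < cg_prob:
                out[i] = G
            else:
                out[i] = others[picks[i]]
        else:
            out[i] = bases[uniform_picks[i]]
        prev_is_c = out[i] == C
    return out


@dataclass
class GeneTruth:
    gene_id: str
    protein_id: str
    pattern: str
    chromosome: str
    start: int
    end: int
    strand: str
    region_introns: list[tuple[int, str, str]]  # (offset, phase, subregion)
    n_introns: int


def gen_gene_models(
    records: list[ProteinRecord],
    truths: list[ProteinTruth],
    spec: CohortSpec,
    seed=0,
    patterns: list[str] | None = None,
) -> tuple[list[GeneModel], dict[str, str], list[GeneTruth]]:
    """Back-translate the cohort into gene models embedded in a genome.

    Returns (gene models, genome {chromosome: sequence}, per-gene truth).
    ``patterns`` overrides the per-gene pattern draw (else drawn from the
    spec's mix).
    """
    spec.validate()
    rng = _rng(seed)
    chrom_names = list(spec.genome.chromosomes)
    genome_arrays = {}
    for chrom in chrom_names:
        parts = [
            _markov_sequence(length, p, rng)
            for length, p in spec.genome.chromosomes[chrom]
        ]
        genome_arrays[chrom] = np.concatenate(parts)

    if patterns is None:
        keys = list(spec.pattern_mix)
        mix = np.array([spec.pattern_mix[k] for k in keys])
        patterns = [str(rng.choice(keys, p=mix)) for _ in records]

    n_per_chrom = -(-len(records) // len(chrom_names))
    models: list[GeneModel] = []
    gene_truths: list[GeneTruth] = []
    for idx, (rec, truth, pattern) in enumerate(zip(records, truths, patterns)):
        gene_id = rec.id.replace("SYNbZIP", "SYNgene") if "SYNbZIP" in rec.id else rec.id + "_g"
        cds = "".join(CODON[aa] for aa in rec.sequence)
        offsets = _intron_offsets_for_pattern(pattern, truth, rng)
        region_introns = []
        spans = {"basic": truth.basic_span, "hinge": truth.hinge_span}
        for off in offsets:
            phase = ("P0", "P1", "P2")[off % 3]
            codon = off // 3 + 1
            sub = next(
                (name for name, s in spans.items() if codon in s), "outside"
            )
            region_introns.append((off, phase, sub))
        if pattern != "h" and rng.random() < spec.extra_intron_prob or (
            pattern == "h" and rng.random() < spec.extra_intron_prob
        ):
            # one extra intron outside the region, in the N-terminal part
            limit = truth.basic_span.start - 1
            if limit >= 3:
                p = int(rng.integers(2, limit + 1))
                offsets = sorted(offsets + [3 * (p - 1)])

        pieces = []
        prev = 0
        intron_lengths = []
        for off in offsets:
            pieces.append(cds[prev:off])
            prev = off
        pieces.append(cds[prev:])
        gene_seq_parts = [pieces[0]]
        for piece in pieces[1:]:
            ilen = int(rng.integers(60, 151))
            intron = "GT" + "".join(
                "ACGT"[int(b)] for b in rng.integers(0, 4, size=ilen - 4)
            ) + "AG"
            intron_lengths.append(len(intron))
            gene_seq_parts.append(intron)
            gene_seq_parts.append(piece)
        gene_seq = "".join(gene_seq_parts)

        chrom = chrom_names[idx // n_per_chrom]
        within = idx % n_per_chrom
        chrom_len = len(genome_arrays[chrom])
        slot = (chrom_len - 20_000) // n_per_chrom
        start0 = 10_000 + within * slot  # 0-based insertion point
        if start0 + len(gene_seq) > chrom_len:
            raise ValueError("genome too small for cohort placement")
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = gene_seq if strand == "+" else revcomp(gene_seq)
        genome_arrays[chrom][start0 : start0 + len(gene_seq)] = np.frombuffer(
            inserted.encode("ascii"), dtype=np.uint8
        )
        gene_start = start0 + 1  # 1-based
        gene_end = start0 + len(gene_seq)

        # exon layout within the forward gene sequence (0-based, half-open)
        exon_local = []
        cursor = 0
        for i, piece in enumerate(pieces):
            exon_local.append((cursor, cursor + len(piece)))
            cursor += len(piece)
            if i < len(intron_lengths):
                cursor += intron_lengths[i]
        if strand == "+":
            segments = [
                Span(gene_start + lo, gene_start + hi - 1) for lo, hi in exon_local
            ]
        else:
            segments = [
                Span(gene_end - hi + 1, gene_end - lo) for lo, hi in exon_local
            ]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                cds_segments=segments,
                protein_id=rec.id,
            )
        )
        gene_truths.append(
            GeneTruth(
                gene_id=gene_id,
                protein_id=rec.id,
                pattern=pattern,
                chromosome=chrom,
                start=gene_start,
                end=gene_end,
                strand=strand,
                region_introns=region_introns,
                n_introns=len(offsets),
            )
        )
    genome = {
        chrom: arr.tobytes().decode("ascii") for chrom, arr in genome_arrays.items()
    }
    return models, genome, gene_truths


def gene_truth_table(gene_truths: list[GeneTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "protein_id": t.protein_id,
                "pattern": t.pattern,
                "chromosome": t.chromosome,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "region_introns": ";".join(
                    f"{o}:{ph}:{sub}" for o, ph, sub in t.region_introns
                ),
                "n_introns": t.n_introns,
            }
            for t in gene_truths
        ]
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables


#: Cluster archetype sign patterns over the 14 default conditions, chosen to
#: mirror the observed cluster behaviours (I: down everywhere except ABA/MeJA;
#: II: up under environmental + phytohormone, down under heavy metal; III/IV:
#: contrasting group-level patterns).
_ARCHETYPES = {
    0: [-1] * 12 + [1, 1],
    1: [1] * 5 + [-1] * 5 + [1] * 4,
    2: [1] * 10 + [-1] * 4,
    3: [-1, 1] * 7,
}


def gen_ct_table(
    design: ExpressionDesign, seed=0
) -> tuple[CtTable, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Generate a replicate-level Ct table with planted cluster structure.

    Returns ``(ct_table, planted_labels, planted_effects, condition_meta)``
    where ``planted_effects`` holds the planted -ddCT per gene x condition.
    """
    rng = _rng(seed)
    conditions = list(design.conditions)
    if len(_ARCHETYPES[0]) != len(conditions):
        # non-default condition sets get random sign archetypes
        archetypes = {
            c: list(rng.choice([-1, 1], size=len(conditions)))
            for c in range(design.k)
        }
    else:
        archetypes = {c: _ARCHETYPES[c % 4] for c in range(design.k)}
    genes = [f"SYNgene{i + 1:03d}" for i in range(design.n_genes)]
    labels = pd.Series(
        [i * design.k // design.n_genes for i in range(design.n_genes)],
        index=genes, name="planted_cluster",
    )
    half = design.separation / 2.0
    effects = pd.DataFrame(
        [[archetypes[labels[g]][j] * half for j in range(len(conditions))]
         for g in genes],
        index=genes, columns=conditions,
    )
    rows = []
    ref_ct = 18.0
    base_ct = {g: 20.0 + float(rng.normal(0, 1.0)) for g in genes}
    all_conditions = [design.calibrator_condition_id] + conditions
    for cond in all_conditions:
        for rep in range(1, design.replicates + 1):
            rows.append(
                {"gene_id": design.reference_gene_id, "condition_id": cond,
                 "replicate": rep, "ct": ref_ct}
            )
    for g in genes:
        for cond in all_conditions:
            effect = 0.0 if cond == design.calibrator_condition_id else effects.at[g, cond]
            mean_ct = base_ct[g] - effect  # -ddCT = effect when ref constant
            for rep in range(1, design.replicates + 1):
                noise = float(rng.normal(0, design.noise_sd)) if design.noise_sd else 0.0
                rows.append(
                    {"gene_id": g, "condition_id": cond, "replicate": rep,
                     "ct": mean_ct + noise}
                )
    table = CtTable(
        pd.DataFrame(rows),
        reference_gene_id=design.reference_gene_id,
        calibrator_condition_id=design.calibrator_condition_id,
    )
    meta = pd.DataFrame(
        [{"condition_id": c, "group": g, "tissue": "seedling"}
         for c, g in design.conditions.items()]
    )
    return table, labels, effects, meta
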