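"""Intron splicing phases and pattern classification in the basic+hinge region.

An intron's splicing phase is where it interrupts the reading frame: P0
between two codons, P1 after the first nucleotide of a codon, P2 after the
second. Introns falling within the basic region or hinge of the bZIP domain
are classified into eight patterns (a-h) by their count, sub-region and
phase; pattern h is the region-intronless class. The default rule table:

========  ======================================================
pattern   rule (region introns only; no P1 pattern exists)
========  ======================================================
a         1 intron, basic region, P2
b         1 intron, hinge, P0
c         1 intron, basic region, P0
d         1 intron, hinge, P2
e         2 introns not matching f or g (mixed phases/sub-regions)
f         2 introns, both P0, both in the basic region
g         2 introns, both P0, spanning basic and hinge
h         no introns in the region
========  ======================================================

Anything else (any P1 region intron, or >2 region introns) is unclassified.
The table is overridable via :class:`PatternRules`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .domain_scan import BzipDomainAnnotation
from .io import GeneModel, junction_codon

PHASES = ("P0", "P1", "P2")
PATTERNS = ("a", "b", "c", "d", "e", "f", "g", "h")


@dataclass(frozen=True)
class IntronRecord:
    """One splice junction: CDS offset, phase, and bZIP sub-region."""

    gene_id: str
    coding_offset: int  # CDS nucleotides preceding the junction
    phase: str  # P0 | P1 | P2
    subregion: str = "unset"  # basic | hinge | outside | unset

    def __post_init__(self) -> None:
        expected = PHASES[self.coding_offset % 3]
        if self.phase != expected:
            raise ValueError(
                f"{self.gene_id}: phase {self.phase} inconsistent with "
                f"coding offset {self.coding_offset} (expected {expected})"
            )


@dataclass
class IntronPatternCall:
    gene_id: str
    region_introns: list[IntronRecord]
    pattern: str  # a..h | unclassified
    gene_intron_count: int
    intronless: bool
    flags: list[str] = field(default_factory=list)


def extract_introns(model: GeneModel) -> list[IntronRecord]:
    """One record per junction between consecutive CDS segments.

    Works in translation order, so plus- and minus-strand genes with the
    same exon structure yield identical offsets and phases.
    """
    records = []
    offset = 0
    for segment in model.cds_segments[:-1]:
        offset += len(segment)
        records.append(
            IntronRecord(model.gene_id, offset, PHASES[offset % 3])
        )
    return records


def locate_in_domain(
    introns: list[IntronRecord], domain: BzipDomainAnnotation | None
) -> tuple[list[IntronRecord], list[str]]:
    """Set each intron's sub-region from the protein-level domain spans.

    Protein position *p* covers CDS nucleotides 3p-2..3p; a P0 junction
    exactly between two codons belongs to the codon on its 3' side. With a
    null domain annotation everything is ``outside`` and the gene flagged.
    """
    flags: list[str] = []
    if domain is None or not domain.has_domain:
        flags.append("no_domain_annotation")
        return (
            [IntronRecord(r.gene_id, r.coding_offset, r.phase, "outside") for r in introns],
            flags,
        )
    located = []
    for r in introns:
        codon = junction_codon(r.coding_offset)
        if codon in domain.basic_span:
            sub = "basic"
        elif codon in domain.hinge_span:
            sub = "hinge"
        else:
            sub = "outside"
        located.append(IntronRecord(r.gene_id, r.coding_offset, r.phase, sub))
    return located, flags


@dataclass
class PatternRules:
    """Editable pattern rule table; keys are (count, tuple of (subregion, phase))."""

    one_intron: dict = field(
        default_factory=lambda: {
            ("basic", "P2"): "a",
            ("hinge", "P0"): "b",
            ("basic", "P0"): "c",
            ("hinge", "P2"): "d",
        }
    )

    def classify(self, region_introns: list[IntronRecord]) -> tuple[str, list[str]]:
        flags: list[str] = []
        n = len(region_introns)
        if n == 0:
            return "h", flags
        if any(r.phase == "P1" for r in region_introns):
            return "unclassified", ["p1_intron_in_region"]
        if n == 1:
            r = region_introns[0]
            return self.one_intron.get((r.subregion, r.phase), "unclassified"), flags
        if n == 2:
            phases = {r.phase for r in region_introns}
            subs = sorted(r.subregion for r in region_introns)
            if phases == {"P0"}:
                if subs == ["basic", "basic"]:
                    return "f", flags
                if subs == ["basic", "hinge"]:
                    return "g", flags
            return "e", flags
        return "unclassified", ["more_than_two_region_introns"]


def classify_pattern(
    gene_id: str,
    introns: list[IntronRecord],
    domain: BzipDomainAnnotation | None,
    rules: PatternRules | None = None,
) -> IntronPatternCall:
    """Full per-gene call: locate introns in the domain and assign a-h."""
    rules = rules or PatternRules()
    located, flags = locate_in_domain(introns, domain)
    region = [r for r in located if r.subregion in ("basic", "hinge")]
    if domain is None or not domain.has_domain:
        pattern = "unclassified"
    else:
        pattern, rule_flags = rules.classify(region)
        flags.extend(rule_flags)
    return IntronPatternCall(
        gene_id=gene_id,
        region_introns=region,
        pattern=pattern,
        gene_intron_count=len(introns),
        intronless=len(introns) == 0,
        flags=flags,
    )


def pattern_census(calls: list[IntronPatternCall]) -> dict:
    """Cohort summary: per-pattern counts plus intron bookkeeping."""
    patterns = Counter(c.pattern for c in calls)
    return {
        "n_genes": len(calls),
        "patterns": {p: patterns.get(p, 0) for p in PATTERNS},
        "unclassified": patterns.get("unclassified", 0),
        "genes_with_introns": sum(not c.intronless for c in calls),
        "intronless_genes": sum(c.intronless for c in calls),
        "genes_with_1_2_region_introns": sum(
            1 <= len(c.region_introns) <= 2 for c in calls
        ),
    }


def pattern_report(calls: list[IntronPatternCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "gene_intron_count": c.gene_intron_count,
                "region_introns": ";".join(
                    f"{r.coding_offset}:{r.phase}:{r.subregion}"
                    for r in c.region_introns
                ),
                "pattern": c.pattern,
                "intronless": c.intronless,
                "flags": ";".join(c.flags),
            }
            for c in calls
        ]
    )
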