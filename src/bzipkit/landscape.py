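"""Genome CpG-density windowing, gene-to-window assignment, and duplicate pairs.

CpG dinucleotides are counted in fixed windows (default 100 kb) along each
chromosome with an overlapping scan; a window's density is the count over
its effective (non-N) length, and windows above the genome-wide top
quartile are labelled high-CpG. Candidate duplicate gene pairs come from
all-vs-all global alignment of bZIP-domain subsequences, with a pair called
tandem when both genes sit on one chromosome within a maximal separation
(default 100 kb), segmental otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .domain_scan import BzipDomainAnnotation
from .io import ProteinRecord, Span


@dataclass
class Window:
    start: int  # 1-based inclusive
    end: int
    cpg_count: int
    effective_length: int  # non-N bases
    cls: str = "low"  # high | low

    @property
    def density(self) -> float:
        return self.cpg_count / self.effective_length if self.effective_length else 0.0


@dataclass
class CpGProfile:
    chromosome: str
    window_size: int
    windows: list[Window] = field(default_factory=list)


def cpg_windows(
    sequence: str, chromosome: str, window_size: int = 100_000
) -> CpGProfile:
    """Tile a chromosome into windows and count CpG ("CG") dinucleotides.

    The scan is overlapping and case-insensitive; a pair spanning a window
    boundary is assigned to the window containing the C. N positions are
    excluded from each window's effective length.
    """
    profile = CpGProfile(chromosome, window_size)
    if not sequence:
        return profile
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    n_windows = -(-len(arr) // window_size)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    cg_at = np.flatnonzero(is_c[:-1] & is_g[1:]) if len(arr) > 1 else np.array([], int)
    cg_per_window = np.bincount(cg_at // window_size, minlength=n_windows)
    non_n = np.flatnonzero(arr != ord("N"))
    eff_per_window = np.bincount(non_n // window_size, minlength=n_windows)
    for w in range(n_windows):
        start = w * window_size + 1
        end = min(len(arr), (w + 1) * window_size)
        profile.windows.append(
            Window(start, end, int(cg_per_window[w]), int(eff_per_window[w]))
        )
    return profile


def classify_windows(
    profiles: list[CpGProfile], quantile: float = 0.75
) -> list[CpGProfile]:
    """Label windows high/low CpG by genome-wide density quantile.

    A window is high iff its density is strictly above the genome-wide
    ``quantile`` of window densities (so uniform genomes have no high
    windows). Requires at least 4 windows genome-wide. Mutates and returns
    the profiles.
    """
    densities = [w.density for p in profiles for w in p.windows]
    if len(densities) < 4:
        raise ValueError("need at least 4 windows genome-wide to classify")
    threshold = float(np.quantile(densities, quantile))
    for p in profiles:
        for w in p.windows:
            w.cls = "high" if w.density > threshold else "low"
    return profiles


def assign_genes(
    profiles: list[CpGProfile],
    gene_positions: dict[str, tuple[str, int, int]],
) -> pd.DataFrame:
    """Assign each gene to the window containing its midpoint.

    ``gene_positions`` maps gene_id -> (chromosome, start, end), 1-based
    inclusive. Window ownership is half-open: a midpoint exactly on a
    window's first base belongs to that window. Out-of-bounds genes raise.
    """
    by_chrom = {p.chromosome: p for p in profiles}
    rows = []
    for gene_id, (chrom, start, end) in gene_positions.items():
        if chrom not in by_chrom:
            raise ValueError(f"gene {gene_id}: unknown chromosome {chrom!r}")
        profile = by_chrom[chrom]
        midpoint = (start + end) // 2
        chrom_end = profile.windows[-1].end if profile.windows else 0
        if not 1 <= midpoint <= chrom_end:
            raise ValueError(
                f"gene {gene_id}: midpoint {midpoint} outside chromosome "
                f"{chrom!r} (length {chrom_end})"
            )
        widx = (midpoint - 1) // profile.window_size
        window = profile.windows[widx]
        rows.append(
            {
                "gene_id": gene_id,
                "chromosome": chrom,
                "midpoint": midpoint,
                "window_index": widx + 1,
                "window_start": window.start,
                "window_class": window.cls,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity: float
    same_chromosome: bool
    genomic_gap: int | None  # bp between nearer gene ends; None across chromosomes
    mode: str  # tandem | segmental


def _domain_subsequence(
    protein: ProteinRecord, annotation: BzipDomainAnnotation
) -> str | None:
    if not annotation.has_domain:
        return None
    end_span = annotation.zipper_span or annotation.hinge_span
    return protein.sequence[annotation.basic_span.start - 1 : end_span.end]


def domain_identity(domain_a: str, domain_b: str) -> float:
    """Identity of a global alignment (match +1, mismatch 0, linear gap -1)."""
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    alignment = aligner.align(domain_a, domain_b)[0]
    a_row, b_row = alignment[0], alignment[1]
    matches = sum(x == y and x != "-" for x, y in zip(a_row, b_row))
    return matches / len(a_row)


def find_duplicate_pairs(
    proteins: list[ProteinRecord],
    annotations: dict[str, BzipDomainAnnotation],
    gene_positions: dict[str, tuple[str, int, int]],
    identity_min: float = 0.7,
    max_block: int = 100_000,
    protein_to_gene: dict[str, str] | None = None,
) -> list[DuplicatePair]:
    """All-vs-all duplicate detection over bZIP-domain subsequences.

    Pairs at domain identity >= ``identity_min`` are reported; a pair is
    tandem iff both genes share a chromosome and their separation (bp
    between nearer ends, 0 when overlapping) is <= ``max_block``, else
    segmental. Proteins without a domain annotation are skipped.
    """
    protein_to_gene = protein_to_gene or {}
    usable = []
    for p in proteins:
        ann = annotations.get(p.id)
        if ann is None or not ann.has_domain:
            continue
        gene_id = protein_to_gene.get(p.id, p.id)
        if gene_id not in gene_positions:
            continue
        usable.append((gene_id, _domain_subsequence(p, ann)))
    pairs: list[DuplicatePair] = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            (gene_a, dom_a), (gene_b, dom_b) = usable[i], usable[j]
            identity = domain_identity(dom_a, dom_b)
            if identity < identity_min:
                continue
            chrom_a, start_a, end_a = gene_positions[gene_a]
            chrom_b, start_b, end_b = gene_positions[gene_b]
            same = chrom_a == chrom_b
            if same:
                gap = max(0, max(start_a, start_b) - min(end_a, end_b) - 1)
            else:
                gap = None
            mode = "tandem" if same and gap <= max_block else "segmental"
            pairs.append(DuplicatePair(gene_a, gene_b, identity, same, gap, mode))
    return pairs


# ---------------------------------------------------------------------------
# TSV reports


def cpg_report(profiles: list[CpGProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": p.chromosome,
                "start": w.start,
                "end": w.end,
                "cpg_count": w.cpg_count,
                "effective_length": w.effective_length,
                "density": w.density,
                "class": w.cls,
            }
            for p in profiles
            for w in p.windows
        ]
    )


def duplicate_report(
    pairs: list[DuplicatePair], kaks: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Duplicate-pair table; optional Ka/Ks columns joined from input."""
    df = pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "identity": p.identity,
                "same_chromosome": p.same_chromosome,
                "genomic_gap": "" if p.genomic_gap is None else p.genomic_gap,
                "mode": p.mode,
            }
            for p in pairs
        ]
    )
    if kaks is not None and not df.empty:
        df = df.merge(kaks, how="left", on=["gene_a", "gene_b"])
    return df
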