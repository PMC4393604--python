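"""Locate the bZIP domain anatomy on a protein and assign the heptad register.

The bZIP domain is modelled as three consecutive parts:

* **basic region** — the conserved DNA-binding motif ``N-x7-R/K`` (an
  invariant asparagine, seven arbitrary residues, then arginine or lysine);
* **hinge** — the nine residues immediately C-terminal of the invariant
  R/K (the ``x9`` tail of the canonical ``N-x7-R/K-x9`` description);
* **leucine zipper** — a coiled-coil of 4-9 heptad repeats whose positions
  are labelled a-g, with the first zipper leucine anchored at position *d*
  of heptad 1.

The zipper demarcation automates the manual convention used for plant bZIP
surveys: the register anchor is the first leucine (fallback: first I/V/M)
after the hinge, and the zipper runs C-terminally heptad by heptad until the
sequence ends, a cap of nine heptads is reached, or two consecutive heptads
carry no hydrophobic residue at either *a* or *d*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io import ProteinRecord, Span

#: Residues counted as hydrophobic at the a/d coiled-coil interface.
HYDROPHOBIC = frozenset("LIVMFA")

#: Heptad position labels in N-to-C order starting at position a.
HEPTAD_POSITIONS = ("a", "b", "c", "d", "e", "f", "g")

BASIC_MOTIF = re.compile(r"(?=(N.{7}[RK]))")

HINGE_LENGTH = 9
BASIC_LENGTH = 9  # N + x7 + R/K


@dataclass
class ScanConfig:
    """Tunable thresholds of the domain scan."""

    anchor_search_window: int = 15  # residues after the hinge searched for L
    min_heptads: int = 4
    max_heptads: int = 9
    degenerate_run: int = 2  # consecutive a/d-degenerate heptads ending the zipper
    hydrophobic: frozenset = HYDROPHOBIC


@dataclass
class BzipDomainAnnotation:
    """Spans of basic region, hinge, and leucine zipper, plus the register.

    ``register_anchor`` is the protein position (1-based) of the residue
    assigned to position *d* of heptad 1. A protein without a canonical
    basic region or zipper carries ``None`` spans and explanatory flags.
    """

    protein_id: str
    basic_span: Span | None
    hinge_span: Span | None
    zipper_span: Span | None
    register_anchor: int | None
    flags: list[str] = field(default_factory=list)

    @property
    def has_domain(self) -> bool:
        return self.basic_span is not None

    @property
    def has_zipper(self) -> bool:
        return self.zipper_span is not None


@dataclass
class HeptadTable:
    """Per-heptad residues keyed by position labels a-g.

    ``heptads[i]`` (0-based list, heptad index i+1) maps each label to a
    residue, or ``None`` for slots outside the zipper span / sequence.
    Heptads with any empty slot are flagged partial.
    """

    protein_id: str
    heptads: list[dict[str, str | None]]
    partial: list[bool]

    @property
    def n_heptads(self) -> int:
        return len(self.heptads)

    @property
    def n_full(self) -> int:
        return sum(not p for p in self.partial)

    def slot(self, heptad_index: int, position: str) -> str | None:
        """Residue at 1-based heptad index and position label."""
        return self.heptads[heptad_index - 1][position]


def find_basic_region(protein: ProteinRecord) -> Span | None:
    """Find the ``N-x7-R/K`` basic region, or ``None`` if absent.

    Among multiple motif matches, the winner is the one whose 18-residue
    window (basic region plus hinge) contains the most R+K residues, ties
    going to the leftmost match. Matches whose hinge would run past the
    sequence end are not considered.
    """
    seq = protein.sequence
    if len(seq) < 25:
        return None
    best: tuple[int, int] | None = None  # (-score, start) for min()
    for m in BASIC_MOTIF.finditer(seq):
        start = m.start()  # 0-based index of the N
        if start + BASIC_LENGTH + HINGE_LENGTH > len(seq):
            continue
        window = seq[start : start + BASIC_LENGTH + HINGE_LENGTH]
        score = window.count("R") + window.count("K")
        key = (-score, start)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    start = best[1]
    return Span(start + 1, start + BASIC_LENGTH)


def hinge_span_for(basic_span: Span) -> Span:
    """The x9 hinge immediately C-terminal of the basic region."""
    return Span(basic_span.end + 1, basic_span.end + HINGE_LENGTH)


def demarcate_zipper(
    protein: ProteinRecord,
    basic_span: Span,
    config: ScanConfig | None = None,
) -> tuple[Span | None, int | None, list[str]]:
    """Place the leucine zipper and its register anchor after the hinge.

    Returns ``(zipper_span, register_anchor, flags)``. The anchor is the
    first L (fallback I/V/M) within ``anchor_search_window`` residues after
    the hinge; it becomes position *d* of heptad 1, so the zipper begins at
    ``anchor - 3`` (position *a*, clipped at the sequence start, in which
    case heptad 1 is partial). Extension stops at the sequence end, at
    ``max_heptads``, or just before a run of ``degenerate_run`` consecutive
    heptads with no hydrophobic residue at *a* or *d*.
    """
    cfg = config or ScanConfig()
    seq = protein.sequence
    flags: list[str] = []
    hinge_end = basic_span.end + HINGE_LENGTH  # 1-based
    lo = hinge_end  # 0-based index of first residue after the hinge
    hi = min(len(seq), lo + cfg.anchor_search_window)
    window = seq[lo:hi]
    anchor0 = None
    idx = window.find("L")
    if idx >= 0:
        anchor0 = lo + idx
    else:
        for fallback in "IVM":
            idx = window.find(fallback)
            if idx >= 0 and (anchor0 is None or lo + idx < anchor0):
                anchor0 = lo + idx
        if anchor0 is not None:
            flags.append("anchor_fallback_ivm")
    if anchor0 is None:
        return None, None, ["no_zipper_anchor"]
    anchor = anchor0 + 1  # 1-based position of heptad-1 d

    zipper_start = anchor - 3
    if zipper_start < 1:
        flags.append("partial_first_heptad")
        zipper_start = 1
    register_start = anchor - 3  # may be < 1; defines the a-slot of heptad 1

    def residue(pos: int) -> str | None:
        return seq[pos - 1] if 1 <= pos <= len(seq) else None

    statuses: list[bool] = []  # per included heptad: degenerate at a/d?
    for i in range(1, cfg.max_heptads + 1):
        h_start = register_start + 7 * (i - 1)
        h_end = h_start + 6
        if h_start > len(seq):
            break
        a, d = residue(h_start), residue(h_start + 3)
        full = h_start >= 1 and h_end <= len(seq)
        is_degenerate = full and (
            a not in cfg.hydrophobic and d not in cfg.hydrophobic
        )
        statuses.append(is_degenerate)
        if len(statuses) >= cfg.degenerate_run and all(
            statuses[-cfg.degenerate_run :]
        ):
            break
        if not full:
            break
    # the zipper never ends in degenerate heptads: trim any trailing run
    if statuses and statuses[-1]:
        flags.append("terminated_by_degenerate_heptads")
        while statuses and statuses[-1]:
            statuses.pop()
    included = len(statuses)

    if included < cfg.min_heptads:
        return None, None, flags + ["no_zipper_short"]
    zipper_end = min(len(seq), register_start + 7 * included - 1)
    return Span(zipper_start, zipper_end), anchor, flags


def build_heptad_table(
    protein: ProteinRecord, zipper_span: Span, register_anchor: int
) -> HeptadTable:
    """Assign zipper residues cyclically to heptad slots a-g.

    Heptad 1 position *a* is ``register_anchor - 3``; slots falling before
    the zipper span or past the sequence end are stored empty and flag the
    heptad partial. The table has ``ceil(zipper length / 7)`` heptads.
    """
    seq = protein.sequence
    register_start = register_anchor - 3
    # Number of heptads needed to cover the span from the register origin.
    n = -(-(zipper_span.end - register_start + 1) // 7)
    heptads: list[dict[str, str | None]] = []
    partial: list[bool] = []
    for i in range(n):
        row: dict[str, str | None] = {}
        for j, label in enumerate(HEPTAD_POSITIONS):
            pos = register_start + 7 * i + j
            if pos < zipper_span.start or pos > zipper_span.end or pos > len(seq):
                row[label] = None
            else:
                row[label] = seq[pos - 1]
        heptads.append(row)
        partial.append(any(v is None for v in row.values()))
    return HeptadTable(protein.id, heptads, partial)


def scan_protein(
    protein: ProteinRecord, config: ScanConfig | None = None
) -> tuple[BzipDomainAnnotation, HeptadTable | None]:
    """Full scan: basic region, hinge, zipper, and heptad table."""
    basic = find_basic_region(protein)
    if basic is None:
        ann = BzipDomainAnnotation(
            protein.id, None, None, None, None, ["no_canonical_basic_region"]
        )
        return ann, None
    hinge = hinge_span_for(basic)
    zipper, anchor, flags = demarcate_zipper(protein, basic, config)
    ann = BzipDomainAnnotation(protein.id, basic, hinge, zipper, anchor, flags)
    table = None
    if zipper is not None:
        table = build_heptad_table(protein, zipper, anchor)
    return ann, table


def scan_report(annotations) -> "pd.DataFrame":  # noqa: F821
    """Tabular TSV-ready report of domain annotations."""
    import pandas as pd

    rows = []
    for ann, table in annotations:
        rows.append(
            {
                "protein_id": ann.protein_id,
                "basic_start": ann.basic_span.start if ann.basic_span else "",
                "basic_end": ann.basic_span.end if ann.basic_span else "",
                "hinge_start": ann.hinge_span.start if ann.hinge_span else "",
                "hinge_end": ann.hinge_span.end if ann.hinge_span else "",
                "zipper_start": ann.zipper_span.start if ann.zipper_span else "",
                "zipper_end": ann.zipper_span.end if ann.zipper_span else "",
                "register_anchor": ann.register_anchor or "",
                "n_heptads": table.n_heptads if table else 0,
                "flags": ";".join(ann.flags),
            }
        )
    return pd.DataFrame(rows)
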