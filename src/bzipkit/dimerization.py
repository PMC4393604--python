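"""Leucine-zipper dimerization statistics and sub-family classification.

Dimerization specificity of bZIP coiled-coils is read off the heptad table:
charged residues at positions *g* and *e* form interhelical g<->e salt
bridges (attractive when opposite charges, repulsive when like charges),
asparagines at interface position *a* favour homo-dimerization, and leucines
at *d* stabilise the dimer. Pooled position compositions, per-heptad Asn
frequencies, and per-heptad g<->e pair-class histograms are computed across
a cohort, and each protein is scored into sub-family I (homo-favouring),
II (hetero-favouring) or III (ambivalent).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .domain_scan import HeptadTable

ACIDIC = frozenset("DE")
BASIC_DEFAULT = frozenset("RK")
HYDROPHOBIC = frozenset("AFILMV")

PAIR_CLASSES = ("attractive", "repulsive", "incomplete", "none")
RESIDUE_CLASSES = ("acidic", "basic", "polar", "hydrophobic", "other")


def residue_class(residue: str, include_his_basic: bool = False) -> str:
    """Map a residue to {acidic, basic, polar, hydrophobic, other}.

    Classes are disjoint and exhaustive over the 20 letters; histidine is
    polar by default (weakly charged under the coiled-coil pairing rules)
    and counted basic only when ``include_his_basic`` is set.
    """
    basic = BASIC_DEFAULT | ({"H"} if include_his_basic else frozenset())
    if residue in ACIDIC:
        return "acidic"
    if residue in basic:
        return "basic"
    if residue in HYDROPHOBIC:
        return "hydrophobic"
    if residue in "CGNQSTWY" or residue == "H":
        return "polar"
    return "other"  # proline


@dataclass(frozen=True)
class GePairCall:
    """Electrostatic class of the g(i) <-> e(i+1) interhelical pair."""

    heptad_index: int  # pair spans heptads i and i+1
    g_residue: str
    e_residue: str
    call: str  # attractive | repulsive | incomplete | none


@dataclass
class DimerizationProfile:
    protein_id: str
    n_full_heptads: int
    ge_calls: list[GePairCall]
    asn_at_a: list[bool]  # per full heptad
    leu_at_d: list[bool]
    charged_at_a: int
    subfamily: str = ""
    flags: list[str] = field(default_factory=list)


def _charge(residue: str, include_his_basic: bool = False) -> str | None:
    cls = residue_class(residue, include_his_basic)
    return cls if cls in ("acidic", "basic") else None


def call_ge_pairs(
    table: HeptadTable, include_his_basic: bool = False
) -> list[GePairCall]:
    """Classify each g(i) <-> e(i+1) pair over the full heptads of a table.

    Pairs touching a partial heptad are skipped (no phantom residues), so a
    table with *n* full leading heptads yields ``n - 1`` calls.
    """
    calls: list[GePairCall] = []
    for i in range(1, table.n_heptads):
        if table.partial[i - 1] or table.partial[i]:
            continue
        g = table.slot(i, "g")
        e = table.slot(i + 1, "e")
        qg, qe = _charge(g, include_his_basic), _charge(e, include_his_basic)
        if qg and qe:
            call = "attractive" if qg != qe else "repulsive"
        elif qg or qe:
            call = "incomplete"
        else:
            call = "none"
        calls.append(GePairCall(i, g, e, call))
    return calls


def position_residue_frequencies(
    tables: list[HeptadTable], position: str
) -> dict[str, float]:
    """Pooled residue frequencies at one heptad position across a cohort.

    Pools all full-heptad slots at ``position``; empty slots and unknown
    residues (X) are excluded from the denominator.
    """
    counts: Counter = Counter()
    for table in tables:
        for i in range(1, table.n_heptads + 1):
            if table.partial[i - 1]:
                continue
            residue = table.slot(i, position)
            if residue and residue != "X":
                counts[residue] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no residues pooled at position {position!r}")
    return {res: n / total for res, n in counts.items()}


def position_composition(
    tables: list[HeptadTable], position: str, include_his_basic: bool = False
) -> dict[str, float]:
    """Class-frequency vector (sums to 1) at a heptad position."""
    freqs = position_residue_frequencies(tables, position)
    out = dict.fromkeys(RESIDUE_CLASSES, 0.0)
    for residue, f in freqs.items():
        out[residue_class(residue, include_his_basic)] += f
    return out


def asn_a_by_heptad(
    tables: list[HeptadTable], max_heptads: int = 9
) -> tuple[dict[int, float], float]:
    """Per-heptad Asn-at-*a* fractions and the combined heptad-2+5 share.

    The per-heptad fraction is the share of proteins carrying N at that
    heptad's *a* slot, among proteins whose zipper reaches that heptad
    (full heptads only). The second return value is the share of all
    a-position asparagines that fall in heptads 2 and 5.
    """
    asn = Counter()
    denom = Counter()
    for table in tables:
        for i in range(1, min(table.n_heptads, max_heptads) + 1):
            if table.partial[i - 1]:
                continue
            residue = table.slot(i, "a")
            if residue is None or residue == "X":
                continue
            denom[i] += 1
            if residue == "N":
                asn[i] += 1
    fractions = {i: asn[i] / denom[i] for i in denom}
    total_asn = sum(asn.values())
    share_2_5 = (asn[2] + asn[5]) / total_asn if total_asn else 0.0
    return fractions, share_2_5


def ge_histogram(all_calls: list[list[GePairCall]]) -> dict[int, Counter]:
    """Per-heptad-index counts of pair classes across a cohort."""
    hist: dict[int, Counter] = {}
    for calls in all_calls:
        for call in calls:
            hist.setdefault(call.heptad_index, Counter())[call.call] += 1
    return hist


@dataclass
class SubfamilyConfig:
    """Thresholds of the homo/hetero-dimerization score."""

    t_hi: float = 0.25
    t_lo: float = -0.25
    w: float = 1.0
    include_his_basic: bool = False


def profile_protein(
    table: HeptadTable, config: SubfamilyConfig | None = None
) -> DimerizationProfile:
    """Compute a per-protein dimerization profile and its sub-family."""
    cfg = config or SubfamilyConfig()
    calls = call_ge_pairs(table, cfg.include_his_basic)
    asn_at_a, leu_at_d = [], []
    charged_at_a = 0
    n_full = 0
    for i in range(1, table.n_heptads + 1):
        if table.partial[i - 1]:
            continue
        n_full += 1
        a, d = table.slot(i, "a"), table.slot(i, "d")
        asn_at_a.append(a == "N")
        leu_at_d.append(d == "L")
        if a and _charge(a, cfg.include_his_basic):
            charged_at_a += 1
    profile = DimerizationProfile(
        protein_id=table.protein_id,
        n_full_heptads=n_full,
        ge_calls=calls,
        asn_at_a=asn_at_a,
        leu_at_d=leu_at_d,
        charged_at_a=charged_at_a,
    )
    profile.subfamily = classify_subfamily(profile, cfg)
    return profile


def homo_score(profile: DimerizationProfile, config: SubfamilyConfig) -> float:
    """Homo-dimerization propensity score in [-2, 2].

    Attractive g<->e pairs and Asn at *a* push toward homo-dimerization;
    repulsive/incomplete pairs and charged residues at *a* push toward
    hetero-dimerization.
    """
    n_pairs = len(profile.ge_calls)
    n_att = sum(c.call == "attractive" for c in profile.ge_calls)
    n_rep = sum(c.call == "repulsive" for c in profile.ge_calls)
    n_inc = sum(c.call == "incomplete" for c in profile.ge_calls)
    pair_term = (n_att - n_rep - n_inc) / max(1, n_pairs)
    heptads = max(1, profile.n_full_heptads)
    asn_term = config.w * sum(profile.asn_at_a) / heptads
    charged_term = config.w * profile.charged_at_a / heptads
    return pair_term + asn_term - charged_term


def classify_subfamily(
    profile: DimerizationProfile, config: SubfamilyConfig | None = None
) -> str:
    """Assign sub-family I (homo), II (hetero) or III (intermediate)."""
    cfg = config or SubfamilyConfig()
    if profile.n_full_heptads < 2:
        profile.flags.append("insufficient_zipper")
        return "III"
    score = homo_score(profile, cfg)
    if score >= cfg.t_hi:
        return "I"
    if score <= cfg.t_lo:
        return "II"
    return "III"


# ---------------------------------------------------------------------------
# TSV reports


def composition_report(tables: list[HeptadTable]) -> pd.DataFrame:
    """Position x class frequency matrix for the g/e/a/d interface positions."""
    rows = []
    for pos in ("g", "e", "a", "d"):
        row = {"position": pos}
        row.update(position_composition(tables, pos))
        rows.append(row)
    return pd.DataFrame(rows)


def asn_report(tables: list[HeptadTable]) -> pd.DataFrame:
    fractions, share = asn_a_by_heptad(tables)
    df = pd.DataFrame(
        [{"heptad": i, "asn_fraction": fractions[i]} for i in sorted(fractions)]
    )
    df.attrs["heptad_2_5_share"] = share
    return df


def ge_report(all_calls: list[list[GePairCall]]) -> pd.DataFrame:
    hist = ge_histogram(all_calls)
    rows = []
    for i in sorted(hist):
        row = {"heptad_pair": i}
        row.update({cls: hist[i].get(cls, 0) for cls in PAIR_CLASSES})
        rows.append(row)
    return pd.DataFrame(rows)


def subfamily_report(profiles: list[DimerizationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "n_full_heptads": p.n_full_heptads,
                "n_attractive": sum(c.call == "attractive" for c in p.ge_calls),
                "n_repulsive": sum(c.call == "repulsive" for c in p.ge_calls),
                "n_incomplete": sum(c.call == "incomplete" for c in p.ge_calls),
                "asn_at_a": sum(p.asn_at_a),
                "charged_at_a": p.charged_at_a,
                "subfamily": p.subfamily,
                "flags": ";".join(p.flags),
            }
            for p in profiles
        ]
    )
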