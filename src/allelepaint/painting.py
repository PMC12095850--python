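"""Haplotype painting over diagnostic sites and genotype classification.

Each haplotype is reduced to a vector of states over the diagnostic
columns — A (matches the ancestral/Clade-I state), D (matches the
derived/Clade-II state), M (missing or an unexpected third allele) — and
categorized as pure ancestral, pure derived, or a mixture (the signature
of a crossover between the two divergent alleles).  Diploid samples are
classified into homozygote-I / homozygote-II / heterozygote /
recombinant, and summaries are produced per lineage.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError
from .io import iupac_expand
from .model import (
    AlignedHaplotype,
    DiagnosticSiteSet,
    GENOTYPE_CATEGORIES,
    LineageAlleleSummary,
    MISSING,
    PaintingResult,
    SampleMetadata,
)

log = logging.getLogger(__name__)


def min_crossovers(states: str) -> int:
    """Minimum number of A<->D switches over all completions of M sites.

    Equals the number of adjacent A-D transitions after deleting the M
    entries (assigning every M run to the state on one side of it).
    """
    informative = [s for s in states if s in "AD"]
    return sum(a != b for a, b in zip(informative, informative[1:]))


def _categorize(states: str) -> str:
    has_a, has_d = "A" in states, "D" in states
    if has_a and has_d:
        return "mixture"
    if has_a:
        return "ancestral"
    if has_d:
        return "derived"
    return "unclassifiable"


def paint_haplotype(
    haplotype: AlignedHaplotype | str,
    diagnostic_sites: DiagnosticSiteSet,
    sample_id: str = "",
    phase: int | str = "unphased",
) -> PaintingResult:
    """State vector of one phased haplotype over the diagnostic sites.

    A base matching neither clade state paints as M and increments the
    third-allele warning counter.
    """
    if isinstance(haplotype, AlignedHaplotype):
        seq, sample_id, phase = haplotype.sequence, haplotype.sample_id, haplotype.phase
    else:
        seq = haplotype
    states = []
    third = 0
    for site in diagnostic_sites:
        if site.column > len(seq):
            raise FormatError(
                f"haplotype of length {len(seq)} does not cover column {site.column}"
            )
        base = seq[site.column - 1].upper()
        if base == site.state_ancestral:
            states.append("A")
        elif base == site.state_derived:
            states.append("D")
        else:
            if base not in MISSING:
                third += 1
            states.append("M")
    s = "".join(states)
    category = _categorize(s)
    return PaintingResult(
        sample_id=sample_id,
        phase=phase,
        states=s,
        category=category,
        min_crossovers=min_crossovers(s) if category == "mixture" else 0,
        n_third_allele=third,
    )


def _site_genotypes(
    unphased: AlignedHaplotype, diagnostic_sites: DiagnosticSiteSet
) -> list[str]:
    """Per-diagnostic-site genotype of an unphased IUPAC sequence:
    'AA', 'DD', 'AD' (het), or 'M'."""
    pairs = iupac_expand(unphased.sequence)
    out = []
    for site in diagnostic_sites:
        bases = pairs[site.column - 1]
        mapped = set()
        for b in bases:
            if b == site.state_ancestral:
                mapped.add("A")
            elif b == site.state_derived:
                mapped.add("D")
            else:
                mapped.add("M")
        if "M" in mapped or bases & MISSING:
            out.append("M")
        elif mapped == {"A"}:
            out.append("AA")
        elif mapped == {"D"}:
            out.append("DD")
        else:
            out.append("AD")
    return out


def classify_unphased(site_genotypes: Sequence[str]) -> str:
    """Genotype category of an unphased diploid from its per-site calls.

    The sample phases into two pure haplotypes iff its non-missing
    diagnostic genotypes are all homozygous-ancestral (homozygote_I),
    all homozygous-derived (homozygote_II), or all heterozygous
    (heterozygote); any other combination forces a mosaic haplotype
    under every one of the 2^h phase assignments, hence recombinant.
    """
    kinds = {g for g in site_genotypes if g != "M"}
    if not kinds:
        return "unclassifiable"
    if kinds == {"AA"}:
        return "homozygote_I"
    if kinds == {"DD"}:
        return "homozygote_II"
    if kinds == {"AD"}:
        return "heterozygote"
    return "recombinant"


def classify_genotype(
    sample_haplotypes: Sequence[AlignedHaplotype],
    diagnostic_sites: DiagnosticSiteSet,
) -> str:
    """Classify one sample from its one (unphased) or two (phased)
    haplotypes."""
    if len(sample_haplotypes) == 1:
        only = sample_haplotypes[0]
        if only.phase == "unphased":
            return classify_unphased(_site_genotypes(only, diagnostic_sites))
        # single phased copy: classify from its own painting
        category = paint_haplotype(only, diagnostic_sites).category
        return {
            "ancestral": "homozygote_I",
            "derived": "homozygote_II",
            "mixture": "recombinant",
            "unclassifiable": "unclassifiable",
        }[category]
    if len(sample_haplotypes) != 2:
        raise FormatError(
            f"sample {sample_haplotypes[0].sample_id!r}: expected two phased "
            f"haplotypes, got {len(sample_haplotypes)}"
        )
    paintings = [paint_haplotype(h, diagnostic_sites) for h in sample_haplotypes]
    cats = sorted(p.category for p in paintings)
    if "mixture" in cats:
        return "recombinant"
    if "unclassifiable" in cats:
        return "unclassifiable"
    if cats == ["ancestral", "ancestral"]:
        return "homozygote_I"
    if cats == ["derived", "derived"]:
        return "homozygote_II"
    return "heterozygote"


def classify_panel(
    haplotypes: Sequence[AlignedHaplotype],
    diagnostic_sites: DiagnosticSiteSet,
) -> dict[str, str]:
    """Per-sample genotype categories for a whole panel."""
    by_sample: dict[str, list[AlignedHaplotype]] = {}
    for h in haplotypes:
        by_sample.setdefault(h.sample_id, []).append(h)
    out = {}
    for sample_id, haps in by_sample.items():
        out[sample_id] = classify_genotype(haps, diagnostic_sites)
        if out[sample_id] == "unclassifiable":
            log.info("sample %s unclassifiable (all diagnostic sites missing)", sample_id)
    return out


def summarize_lineages(
    classified_samples: Mapping[str, str],
    metadata: Mapping[str, SampleMetadata] | Iterable[SampleMetadata],
) -> list[LineageAlleleSummary]:
    """Per-lineage counts and proportions of the genotype categories.

    Proportions are over classified samples; unclassifiable samples are
    counted but excluded from the denominator.
    """
    if not isinstance(metadata, Mapping):
        metadata = {m.sample_id: m for m in metadata}
    by_lineage: dict[str, list[str]] = {}
    for sample_id, category in classified_samples.items():
        meta = metadata.get(sample_id)
        if meta is None:
            raise FormatError(f"classified sample {sample_id!r} absent from metadata")
        by_lineage.setdefault(meta.lineage, []).append(category)

    summaries = []
    for lineage in sorted(by_lineage):
        cats = by_lineage[lineage]
        counts = {c: cats.count(c) for c in GENOTYPE_CATEGORIES}
        denom = len(cats) - counts["unclassifiable"]
        if denom == 0:
            log.warning("lineage %s has no classifiable samples; omitted", lineage)
            continue
        proportions = {
            c: counts[c] / denom
            for c in GENOTYPE_CATEGORIES
            if c != "unclassifiable"
        }
        summaries.append(
            LineageAlleleSummary(
                lineage=lineage,
                n_samples=len(cats),
                counts=counts,
                proportions=proportions,
                denominator=denom,
            )
        )
    return summaries


def summary_frame(summaries: Sequence[LineageAlleleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row: dict[str, object] = {"lineage": s.lineage, "n_samples": s.n_samples}
        for c in GENOTYPE_CATEGORIES:
            row[f"n_{c}"] = s.counts[c]
        for c, p in s.proportions.items():
            row[f"pct_{c}"] = 100.0 * p
        row["denominator"] = s.denominator
        rows.append(row)
    return pd.DataFrame(rows)


_CATEGORY_ORDER = {"ancestral": 0, "derived": 1, "mixture": 2}


def haplotype_catalog(
    paintings: Sequence[PaintingResult],
    lineage_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Distinct painted state vectors with per-lineage counts.

    Rows are sorted by (category, descending total count, states); the
    degenerate all-missing haplotypes are excluded.
    """
    usable = [p for p in paintings if p.category != "unclassifiable"]
    excluded = len(paintings) - len(usable)
    if excluded:
        log.info("%d all-missing haplotype(s) excluded from catalog", excluded)

    lineages = sorted(
        {lineage_of[p.sample_id] for p in usable} if lineage_of else set()
    )
    rows: dict[str, dict[str, object]] = {}
    for p in usable:
        row = rows.setdefault(
            p.states,
            {
                "states": p.states,
                "category": p.category,
                "min_crossovers": p.min_crossovers,
                "total": 0,
                **{f"n_{lin}": 0 for lin in lineages},
            },
        )
        row["total"] = int(row["total"]) + 1
        if lineage_of:
            lin = lineage_of[p.sample_id]
            row[f"n_{lin}"] = int(row[f"n_{lin}"]) + 1

    ordered = sorted(
        rows.values(),
        key=lambda r: (_CATEGORY_ORDER[str(r["category"])], -int(r["total"]), r["states"]),
    )
    return pd.DataFrame(ordered)
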