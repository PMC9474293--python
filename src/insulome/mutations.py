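"""Missense-variant parsing and TF DNA-binding-domain mutation analysis.

Variants arrive as HGVS.p strings with gene and tissue labels; they are
filtered to true missense events, mapped onto per-gene DNA-binding-domain
(DBD) residue ranges, and summarized as positional hotspot landscapes,
amino-acid substitution spectra (relative contribution of each "X>Y" type
per transcription factor or cancer type), and mutation-count rankings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
    # non-missense tokens, recognized so they can be rejected with a label
    "Ter": "*", "Sec": "U",
}

_HGVS_RE = re.compile(
    r"^(?:p\.)?\(?"
    r"(?P<ref>[A-Z][a-z]{2}|[A-Z*])"
    r"(?P<pos>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|[A-Z*=])"
    r"\)?$")


class HgvsRejection(ValueError):
    """Raised for well-formed but non-missense notation; carries a category."""

    def __init__(self, category: str, message: str):
        super().__init__(message)
        self.category = category


def _normalize_aa(token: str) -> str:
    if len(token) == 3:
        if token not in AA3TO1:
            raise HgvsRejection("unparseable", f"unknown residue code {token!r}")
        return AA3TO1[token]
    return token


def parse_hgvs_missense(s: str) -> tuple[str, int, str]:
    """Parse a protein-level HGVS string into (ref_aa, position, alt_aa).

    Accepts 1- or 3-letter residue codes with or without the ``p.`` prefix.
    Nonsense, synonymous, frameshift/indel and other non-missense notations
    raise :class:`HgvsRejection` with a category label so callers can count
    what was filtered.
    """
    s = s.strip()
    low = s.lower()
    for token, cat in (("fs", "frameshift"), ("del", "deletion"),
                       ("ins", "insertion"), ("dup", "duplication"),
                       ("ext", "extension"), ("?", "unknown")):
        if token in low:
            raise HgvsRejection(cat, f"{s!r} is {cat}, not missense")
    m = _HGVS_RE.match(s)
    if not m:
        raise HgvsRejection("unparseable", f"cannot parse HGVS.p {s!r}")
    ref = _normalize_aa(m.group("ref"))
    alt_raw = m.group("alt")
    if alt_raw == "=":
        raise HgvsRejection("synonymous", f"{s!r} is synonymous")
    alt = _normalize_aa(alt_raw)
    if ref == "*" or alt == "*":
        raise HgvsRejection("nonsense", f"{s!r} involves a stop codon")
    if ref not in AA1 or alt not in AA1:
        raise HgvsRejection("unparseable", f"{s!r}: residue outside the "
                            "20-letter alphabet")
    if ref == alt:
        raise HgvsRejection("synonymous", f"{s!r} is synonymous")
    return ref, int(m.group("pos")), alt


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    ref_aa: str
    position: int
    alt_aa: str
    tissue: str = "NS"

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValidationError("ref and alt residues must differ")
        if self.position < 1:
            raise ValidationError("positions are 1-based")
        if self.ref_aa not in AA1 or self.alt_aa not in AA1:
            raise ValidationError("residues must be standard amino acids")

    @property
    def substitution(self) -> str:
        return f"{self.ref_aa}>{self.alt_aa}"


@dataclass(frozen=True)
class TFAnnotation:
    """One representative protein per gene with its DBD residue ranges."""

    gene: str
    protein_length: int
    dbd_class: str
    dbd_ranges: tuple[tuple[int, int], ...]  # 1-based inclusive

    def __post_init__(self) -> None:
        prev_end = 0
        for lo, hi in self.dbd_ranges:
            if lo < 1 or hi > self.protein_length or hi < lo:
                raise ValidationError(
                    f"{self.gene}: DBD range {lo}-{hi} outside protein "
                    f"of length {self.protein_length}")
            if lo <= prev_end:
                raise ValidationError(f"{self.gene}: overlapping DBD ranges")
            prev_end = hi

    def in_dbd(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.dbd_ranges)


def read_variants(path) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Read a TSV (gene, hgvs_p, tissue); returns records + a rejection table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "hgvs_p"):
        if col not in df.columns:
            raise ValidationError(f"variant table needs a {col!r} column")
    records, rejected = [], []
    for row in df.itertuples(index=False):
        tissue = getattr(row, "tissue", "NS") or "NS"
        try:
            ref, pos, alt = parse_hgvs_missense(row.hgvs_p)
        except HgvsRejection as exc:
            rejected.append({"gene": row.gene, "hgvs_p": row.hgvs_p,
                             "category": exc.category})
            continue
        records.append(VariantRecord(row.gene, ref, pos, alt, tissue))
    return records, pd.DataFrame(rejected,
                                 columns=["gene", "hgvs_p", "category"])


def read_tf_table(path) -> dict[str, TFAnnotation]:
    """Read an annotation TSV: gene, length, dbd_class, dbd_ranges ('322-460[,..]')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValidationError(f"duplicate annotation rows for {dupes}; one "
                              "representative transcript per gene is required")
    out = {}
    for row in df.itertuples(index=False):
        ranges = []
        for span in str(row.dbd_ranges).split(","):
            if not span.strip():
                continue
            lo, hi = span.split("-")
            ranges.append((int(lo), int(hi)))
        out[row.gene] = TFAnnotation(row.gene, int(row.length),
                                     row.dbd_class, tuple(ranges))
    return out


def annotate_dbd(variants: Sequence[VariantRecord],
                 annotations: dict[str, TFAnnotation]) -> pd.DataFrame:
    """Flag each variant as in/out of its gene's DBD.

    Returns a DataFrame with columns gene, position, ref_aa, alt_aa, tissue,
    substitution, status — status one of ``dbd`` / ``non_dbd`` /
    ``inconsistent`` (position beyond the annotated protein length) /
    ``unmatched`` (gene absent from the annotation table).  Every input
    variant appears exactly once.
    """
    rows = []
    for v in variants:
        ann = annotations.get(v.gene)
        if ann is None:
            status = "unmatched"
        elif v.position > ann.protein_length:
            status = "inconsistent"
        elif ann.in_dbd(v.position):
            status = "dbd"
        else:
            status = "non_dbd"
        rows.append({"gene": v.gene, "position": v.position,
                     "ref_aa": v.ref_aa, "alt_aa": v.alt_aa,
                     "tissue": v.tissue, "substitution": v.substitution,
                     "status": status})
    return pd.DataFrame(rows, columns=["gene", "position", "ref_aa", "alt_aa",
                                       "tissue", "substitution", "status"])


def position_hotspots(variants: Sequence[VariantRecord], gene: str,
                      top_k: int = 7) -> tuple[pd.Series, list[int]]:
    """Per-residue mutation counts for one gene and the top-k hot positions.

    Ties in count are broken by ascending position.
    """
    positions = [v.position for v in variants if v.gene == gene]
    counts = pd.Series(positions, dtype=int).value_counts().sort_index()
    order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return counts, [pos for pos, _ in order[:top_k]]


@dataclass
class SpectrumResult:
    """Mean +/- SD relative contribution of substitution types across units."""

    per_unit: pd.DataFrame        # units x substitution types, rows sum to 1
    mean: pd.Series
    sd: pd.Series
    top: list[str]
    n_variants: int


def substitution_spectrum(variants: Sequence[VariantRecord],
                          group_by: str = "tf", top_k: int = 9
                          ) -> SpectrumResult:
    """Relative contribution of each amino-acid substitution type.

    Units are transcription factors (``group_by='tf'``) or cancer/tissue
    types (``'cancer_type'``); within each unit the contribution of type
    X>Y is its count divided by the unit's variant count, and the reported
    spectrum is the mean (+/- SD) of those contributions across units.
    ``top`` lists the top_k types by mean contribution (ties broken by
    type name).
    """
    if group_by not in ("tf", "cancer_type"):
        raise ValueError("group_by must be 'tf' or 'cancer_type'")
    if not variants:
        raise ValidationError("no variants to summarize")
    key = (lambda v: v.gene) if group_by == "tf" else (lambda v: v.tissue)
    df = pd.DataFrame({"unit": [key(v) for v in variants],
                       "sub": [v.substitution for v in variants]})
    table = pd.crosstab(df["unit"], df["sub"])
    per_unit = table.div(table.sum(axis=1), axis=0)
    mean = per_unit.mean(axis=0)
    sd = per_unit.std(axis=0, ddof=0)
    order = sorted(mean.index, key=lambda t: (-mean[t], t))
    return SpectrumResult(per_unit=per_unit, mean=mean, sd=sd,
                          top=order[:top_k], n_variants=len(variants))


def rank_entities(annotated: pd.DataFrame, level: str = "tf_all",
                  stratify_by_tissue: bool = False, top_n: int = 20,
                  panels: int = 10):
    """Rank genes by (DBD-)variant count.

    ``level='tf_all'`` counts every matched variant per gene;
    ``'tf_dbd'`` counts only variants with status ``dbd``.  Ties are broken
    alphabetically.  With ``stratify_by_tissue`` the ``panels`` most-mutated
    tissues each get their own sub-ranking, returned as a dict.
    """
    if level not in ("tf_all", "tf_dbd"):
        raise ValueError("level must be 'tf_all' or 'tf_dbd'")
    df = annotated[annotated["status"].isin(["dbd", "non_dbd"])]
    if level == "tf_dbd":
        df = df[df["status"] == "dbd"]

    def ranked(sub: pd.DataFrame) -> pd.DataFrame:
        counts = sub.groupby("gene").size().reset_index(name="count")
        counts = counts.sort_values(["count", "gene"],
                                    ascending=[False, True],
                                    kind="stable").reset_index(drop=True)
        return counts.head(top_n)

    overall = ranked(df)
    if not stratify_by_tissue:
        return overall
    tissue_totals = df.groupby("tissue").size().sort_values(ascending=False)
    top_tissues = sorted(tissue_totals.head(panels).index,
                         key=lambda t: (-tissue_totals[t], t))
    return {"overall": overall,
            "by_tissue": {t: ranked(df[df["tissue"] == t])
                          for t in top_tissues}}


def aa_composition(protein_seq: str) -> pd.DataFrame:
    """Positions (1-based) and overall fraction of each amino acid."""
    seq = protein_seq.strip().upper()
    bad = set(seq) - AA1
    if bad:
        raise ValidationError(f"unknown residues {sorted(bad)} in sequence")
    rows = []
    for aa in sorted(AA1):
        positions = [i + 1 for i, c in enumerate(seq) if c == aa]
        rows.append({"aa": aa, "positions": positions,
                     "count": len(positions),
                     "fraction": len(positions) / len(seq) if seq else 0.0})
    return pd.DataFrame(rows).set_index("aa")
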