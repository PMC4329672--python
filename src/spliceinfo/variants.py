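"""Variant parsing, application, and information-change analysis.

The effect of a sequence change on a binding site is summarized by
``delta_ri = R_i,final - R_i,initial`` (bits).  The minimum fold change in
binding affinity implied by a bit change is ``2^|delta_ri|``; residual
strength is the percent ratio of final to initial information.  Severity
bins follow the Splicing Mutation Calculator convention: a natural site
weakened by more than 7 bits (>= 128-fold) is classed deleterious, -7 to -4
probably deleterious, -4 to -1 leaky, and changes smaller than 1 bit benign
(below the threshold of reliable experimental detection).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .infomodel import BASES, InfoModel, average_information
from .scoring import ScoredSite, score_site, site_span

logger = logging.getLogger(__name__)

SMC_BINS = ("deleterious", "probably_deleterious", "leaky", "benign")

CATEGORIES = (
    "unchanged_above_min",
    "unchanged_below_min",
    "abolished",
    "leaky",
    "cryptic_created",
    "cryptic_strengthened",
    "cryptic_weakened",
)


# ---------------------------------------------------------------------------
# Variant records and parsing
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One sequence change in genomic (sequence) coordinates.

    ``position`` is the 1-based first affected reference base; for a pure
    insertion it is the base *after which* the insertion occurs.
    ``end_position`` carries the last base of a deletion span when the
    deleted bases themselves were not spelled out in the input notation.
    """

    seq_id: str
    position: int
    ref_allele: str = ""
    alt_allele: str = ""
    end_position: int | None = None
    notation_source: str = "genomic"
    original_text: str = ""

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper().replace("U", "T")
        self.alt_allele = self.alt_allele.upper().replace("U", "T")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele and not self.alt_allele and self.end_position is None:
            raise ValueError("variant with both alleles empty and no deletion span")

    @property
    def is_insertion(self) -> bool:
        return not self.ref_allele and self.end_position is None and bool(self.alt_allele)

    def span(self) -> tuple[int, int]:
        """1-based inclusive span of affected reference bases.

        An insertion is assigned the two flanking bases.
        """
        if self.is_insertion:
            return self.position, self.position + 1
        end = self.end_position or self.position + max(len(self.ref_allele), 1) - 1
        return self.position, end


@dataclass
class NaturalSite:
    """An annotated, constitutively used splice site."""

    site_kind: str
    zero_coord: int  # 0-based position of the model zero point
    strand: str = "+"
    name: str = ""


_SUB_RE = re.compile(r"^(\d+)([ACGTUN]+)>([ACGTUN]+)$", re.I)
_DEL_RE = re.compile(r"^(\d+)(?:_(\d+))?del([ACGTUN]*)$", re.I)
_INS_RE = re.compile(r"^(\d+)(?:_(\d+))?ins([ACGTUN]+)$", re.I)
_DELINS_RE = re.compile(r"^(\d+)(?:_(\d+))?delins([ACGTUN]+)$", re.I)
_CDNA_POS_RE = re.compile(r"^(\d+)([+-]\d+)?$")
_IVS_RE = re.compile(r"^IVS(\d+)([+-])(\d+)([ACGTUN])>([ACGTUN])$", re.I)


def _parse_body(body: str, seq_id: str, source: str, original: str) -> VariantRecord:
    m = _DELINS_RE.match(body)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if end < start:
            raise ValueError(f"malformed variant {original!r}: span end before start")
        return VariantRecord(seq_id, start, "", m.group(3), end_position=end,
                             notation_source=source, original_text=original)
    m = _SUB_RE.match(body)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        return VariantRecord(seq_id, pos, ref, alt, notation_source=source, original_text=original)
    m = _INS_RE.match(body)
    if m:
        start = int(m.group(1))
        if m.group(2) is not None and int(m.group(2)) != start + 1:
            raise ValueError(
                f"malformed insertion {original!r}: flanks must be adjacent bases"
            )
        return VariantRecord(seq_id, start, "", m.group(3), notation_source=source,
                             original_text=original)
    m = _DEL_RE.match(body)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else None
        ref = m.group(3)
        if end is not None and end < start:
            raise ValueError(f"malformed variant {original!r}: span end before start")
        if ref:
            if end is not None and end - start + 1 != len(ref):
                raise ValueError(
                    f"malformed deletion {original!r}: span does not match stated bases"
                )
            return VariantRecord(seq_id, start, ref, "", notation_source=source,
                                 original_text=original)
        return VariantRecord(seq_id, start, "", "", end_position=end or start,
                             notation_source=source, original_text=original)
    raise ValueError(f"cannot parse variant text {original!r}")


def cdna_to_genomic(exon_table: pd.DataFrame, cdna_pos: int, intron_offset: int = 0) -> int:
    """Map a cDNA coordinate (with optional +/- intronic offset) to genomic.

    ``exon_table`` has 1-based inclusive columns ``start`` and ``end`` for a
    plus-strand transcript, ordered 5' to 3'.
    """
    if cdna_pos < 1:
        raise ValueError("cDNA positions are 1-based")
    cum = 0
    for _, row in exon_table.iterrows():
        length = int(row["end"]) - int(row["start"]) + 1
        if cdna_pos <= cum + length:
            g = int(row["start"]) + (cdna_pos - cum - 1)
            return g + intron_offset
        cum += length
    raise ValueError(f"cDNA position {cdna_pos} beyond transcript ({cum} nt)")


def parse_variant(
    text: str,
    exon_table: pd.DataFrame | None = None,
    seq_id: str = "",
) -> VariantRecord:
    """Parse a variant string into a canonical genomic-coordinate record.

    Accepted forms: ``seqid:100A>G``, ``seqid:50_52del`` / ``50_52delACG``,
    ``100_101insACT``, ``50_52delinsAA`` (with optional ``g.`` prefix);
    cDNA substitutions ``c.123+2T>C`` and intron-anchored ``IVS2+1G>A``
    (both require ``exon_table``).
    """
    text = text.strip()
    original = text
    sid = seq_id
    if ":" in text:
        sid, text = text.split(":", 1)

    if text.startswith("c."):
        if exon_table is None:
            raise ValueError(f"{original!r}: cDNA notation requires an exon table")
        body = text[2:]
        m = re.match(r"^(\d+)([+-]\d+)?([ACGTUN])>([ACGTUN])$", body, re.I)
        if not m:
            raise ValueError(f"unsupported cDNA notation {original!r} (substitutions only)")
        g = cdna_to_genomic(exon_table, int(m.group(1)),
                            int(m.group(2)) if m.group(2) else 0)
        return VariantRecord(sid, g, m.group(3), m.group(4),
                             notation_source="cdna", original_text=original)

    m = _IVS_RE.match(text)
    if m:
        if exon_table is None:
            raise ValueError(f"{original!r}: IVS notation requires an exon table")
        intron = int(m.group(1))
        sign, k = m.group(2), int(m.group(3))
        if intron >= len(exon_table):
            raise ValueError(f"{original!r}: transcript has no intron {intron}")
        if sign == "+":
            g = int(exon_table.iloc[intron - 1]["end"]) + k
        else:
            g = int(exon_table.iloc[intron]["start"]) - k
        return VariantRecord(sid, g, m.group(4), m.group(5),
                             notation_source="ivs", original_text=original)

    if text.startswith("g."):
        text = text[2:]
    return _parse_body(text, sid, "genomic", original)


def format_variant(v: VariantRecord) -> str:
    """Canonical genomic string form; parse(format(v)) round-trips."""
    prefix = f"{v.seq_id}:" if v.seq_id else ""
    if v.is_insertion:
        return f"{prefix}{v.position}_{v.position + 1}ins{v.alt_allele}"
    start, end = v.span()
    if not v.alt_allele:  # deletion
        coords = f"{start}" if end == start else f"{start}_{end}"
        return f"{prefix}{coords}del{v.ref_allele}"
    if v.ref_allele and len(v.ref_allele) == len(v.alt_allele):
        return f"{prefix}{start}{v.ref_allele}>{v.alt_allele}"
    coords = f"{start}" if end == start else f"{start}_{end}"
    return f"{prefix}{coords}delins{v.alt_allele}"


# ---------------------------------------------------------------------------
# Applying variants
# ---------------------------------------------------------------------------


@dataclass
class AppliedVariant:
    """Mutated sequence plus a monotone old->new coordinate map.

    ``old_to_new[p]`` is the 1-based position in the mutated sequence of
    1-based reference position ``p`` (index 0 unused); deleted positions
    map to -1.
    """

    sequence: str
    old_to_new: np.ndarray

    def map_coord(self, old_pos_1based: int) -> int:
        return int(self.old_to_new[old_pos_1based])

    def map_coord0(self, old_pos_0based: int) -> int:
        """0-based convenience wrapper; returns -1 for deleted positions."""
        new = int(self.old_to_new[old_pos_0based + 1])
        return new - 1 if new > 0 else -1


def apply_variant(reference: str, v: VariantRecord) -> AppliedVariant:
    """Apply ``v`` to ``reference``, validating the stated reference allele."""
    n = len(reference)
    reference = reference.upper().replace("U", "T")

    if v.is_insertion:
        if not 1 <= v.position <= n:
            raise ValueError(f"insertion position {v.position} outside sequence of length {n}")
        ins = v.alt_allele
        mutated = reference[: v.position] + ins + reference[v.position :]
        old_to_new = np.arange(n + 1)
        old_to_new[v.position + 1 :] += len(ins)
        return AppliedVariant(mutated, old_to_new)

    start, end = v.span()
    if end > n:
        raise ValueError(f"variant span [{start}, {end}] outside sequence of length {n}")
    observed = reference[start - 1 : end]
    if v.ref_allele and observed != v.ref_allele:
        raise ValueError(
            f"reference mismatch at {v.seq_id or 'sequence'}:{start}: expected "
            f"{v.ref_allele!r}, observed {observed!r} (check gene isoform/assembly)"
        )
    alt = v.alt_allele
    mutated = reference[: start - 1] + alt + reference[end:]
    old_to_new = np.arange(n + 1)
    span_len = end - start + 1
    if len(alt) == span_len:
        pass  # pure substitution: identity map
    else:
        old_to_new[start : end + 1] = -1
        old_to_new[end + 1 :] += len(alt) - span_len
    return AppliedVariant(mutated, old_to_new)


def invert_variant(reference: str, v: VariantRecord) -> VariantRecord:
    """The variant that exactly undoes ``v`` on ``apply_variant(reference, v)``."""
    start, end = v.span()
    if v.is_insertion:
        return VariantRecord(v.seq_id, v.position + 1, "", "",
                             end_position=v.position + len(v.alt_allele))
    ref_obs = reference.upper()[start - 1 : end]
    if not v.alt_allele:  # deletion -> insert the removed bases back
        return VariantRecord(v.seq_id, start - 1, "", ref_obs)
    return VariantRecord(v.seq_id, start, v.alt_allele, ref_obs)


# ---------------------------------------------------------------------------
# Information-change arithmetic
# ---------------------------------------------------------------------------


@dataclass
class FoldChange:
    """Minimum fold change in binding affinity, 2^|delta_ri|, with direction."""

    fold: float
    direction: str  # 'reduction', 'increase', or 'none'

    def __float__(self) -> float:
        return self.fold


def fold_change(delta_ri: float) -> FoldChange:
    if not math.isfinite(delta_ri):
        raise ValueError("delta_ri must be finite")
    direction = "none" if delta_ri == 0 else ("reduction" if delta_ri < 0 else "increase")
    return FoldChange(fold=2.0 ** abs(delta_ri), direction=direction)


def residual_strength(r_i_final: float, delta_ri: float) -> float | None:
    """Percent residual information, 100 * final / initial.

    Returns None (undefined) when the initial strength is not positive;
    reported alongside the affinity fold change, which it does not replace.
    """
    r_i_initial = r_i_final - delta_ri
    if r_i_initial <= 0:
        return None
    return 100.0 * r_i_final / r_i_initial


def classify_smc(delta_ri: float) -> str:
    """Severity bin from the bit change at a natural site.

    Half-open bins; each boundary belongs to the less severe class (a site
    must be weakened by *more than* 7 bits to be deleterious).
    """
    if not math.isfinite(delta_ri):
        raise ValueError("delta_ri must be finite")
    if delta_ri < -7.0:
        return "deleterious"
    if delta_ri < -4.0:
        return "probably_deleterious"
    if delta_ri < -1.0:
        return "leaky"
    return "benign"


@dataclass
class SiteDelta:
    """Paired pre/post-variant strengths of one model placement."""

    model_name: str
    site_kind: str
    zero_coord: int  # 0-based, pre-variant coordinates
    strand: str
    r_i_initial: float
    r_i_final: float
    is_natural: bool = False
    category: str = "unchanged_below_min"
    smc_bin: str | None = None
    window_span: tuple[int, int] | None = None  # half-open, pre-variant coords

    @property
    def delta_ri(self) -> float:
        return self.r_i_final - self.r_i_initial

    @property
    def min_fold_change(self) -> float:
        return 2.0 ** abs(self.delta_ri)

    @property
    def fold_direction(self) -> str:
        return fold_change(self.delta_ri).direction

    @property
    def residual_strength_pct(self) -> float | None:
        if self.r_i_initial <= 0:
            return None
        return 100.0 * self.r_i_final / self.r_i_initial


def _categorize(
    delta: SiteDelta, r_i_min: float, significance_bits: float
) -> tuple[str, str | None]:
    d = delta.delta_ri
    if delta.is_natural:
        smc = classify_smc(d)
        if delta.r_i_final < r_i_min:
            return "abolished", smc
        if d <= -significance_bits:
            return "leaky", smc
        return ("unchanged_above_min" if delta.r_i_final >= r_i_min
                else "unchanged_below_min"), smc
    if d >= significance_bits and delta.r_i_initial < r_i_min and delta.r_i_final >= r_i_min:
        return "cryptic_created", None
    if d >= significance_bits:
        return "cryptic_strengthened", None
    if d <= -significance_bits:
        return "cryptic_weakened", None
    return ("unchanged_above_min" if delta.r_i_final >= r_i_min
            else "unchanged_below_min"), None


def analyze_variant(
    reference: str,
    v: VariantRecord,
    models,
    natural_sites=(),
    *,
    window_nt: int = 54,
    r_i_min: float = 1.6,
    significance_bits: float = 1.0,
    strand: str = "+",
) -> list[SiteDelta]:
    """Score every model placement around a variant before and after it.

    Placements whose zero coordinate lies within the ``window_nt`` analysis
    window circumscribing the variant are scored on the reference and on the
    mutated sequence (re-anchored through the coordinate map for indels);
    every annotated natural site is always included, so that an engineered
    cryptic site can be compared with its cognate natural site even when the
    latter lies outside the default window.
    """
    models = list(models)
    if not models:
        return []
    max_len = max(m.length for m in models)
    if window_nt < max_len:
        raise ValueError(
            f"analysis window ({window_nt} nt) smaller than the largest model "
            f"window ({max_len} nt)"
        )
    applied = apply_variant(reference, v)
    fstart, fend = v.span()  # 1-based inclusive footprint
    half = window_nt // 2
    z_lo = fstart - 1 - half
    z_hi = fend - 1 + half  # inclusive, 0-based

    natural_lookup = {
        (ns.site_kind, ns.zero_coord, ns.strand) for ns in natural_sites
    }

    deltas: list[SiteDelta] = []
    for model in models:
        zeros = set(range(z_lo, z_hi + 1))
        zeros.update(
            ns.zero_coord for ns in natural_sites
            if ns.site_kind == model.site_kind and ns.strand == strand
        )
        for z in sorted(zeros):
            try:
                pre = score_site(model, reference, z, strand)
            except ValueError:
                continue
            new_z = applied.map_coord0(z)
            if new_z < 0:
                # zero point deleted: re-anchor to the first surviving base
                # to the right so the junction sequence is rescored
                p = z + 1
                while p < len(reference) and applied.map_coord0(p) < 0:
                    p += 1
                new_z = applied.map_coord0(p) if p < len(reference) else -1
            if new_z < 0:
                continue
            try:
                post = score_site(model, applied.sequence, new_z, strand)
            except ValueError:
                continue
            delta = SiteDelta(
                model_name=model.name,
                site_kind=model.site_kind,
                zero_coord=z,
                strand=strand,
                r_i_initial=pre.r_i,
                r_i_final=post.r_i,
                is_natural=(model.site_kind, z, strand) in natural_lookup,
                window_span=site_span(model, z, strand),
            )
            delta.category, delta.smc_bin = _categorize(delta, r_i_min, significance_bits)
            deltas.append(delta)
    if not deltas:
        logger.info("no model placement overlaps variant %s", format_variant(v))
    return deltas


def deltas_to_dataframe(deltas: list[SiteDelta], seq_id: str = "") -> pd.DataFrame:
    """Report table with 1-based coordinates and the full R_i bookkeeping."""
    rows = []
    for d in deltas:
        rows.append(
            {
                "seq_id": seq_id,
                "model": d.model_name,
                "site_kind": d.site_kind,
                "coordinate": d.zero_coord + 1,
                "strand": d.strand,
                "natural": d.is_natural,
                "r_i_initial": d.r_i_initial,
                "r_i_final": d.r_i_final,
                "delta_ri": d.delta_ri,
                "min_fold_change": d.min_fold_change,
                "fold_direction": d.fold_direction,
                "residual_pct": d.residual_strength_pct,
                "category": d.category,
                "smc_bin": d.smc_bin,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Meta-analysis operations
# ---------------------------------------------------------------------------


@dataclass
class PositionSpectrum:
    counts: pd.Series  # indexed by model offset
    correlation: float | None


def position_spectrum(variant_table: pd.DataFrame, model: InfoModel) -> PositionSpectrum:
    """Histogram of deleterious variants per window position, and its Pearson
    correlation with the model's average-information profile.

    ``variant_table`` needs an ``offset`` column; an optional boolean
    ``deleterious`` column restricts the count.  The correlation is undefined
    (None) with fewer than 3 distinct offsets.
    """
    table = variant_table
    if "deleterious" in table.columns:
        table = table[table["deleterious"].astype(bool)]
    offsets = table["offset"].astype(int)
    lo, hi = model.offset_start, model.offset_end
    if ((offsets < lo) | (offsets > hi)).any():
        bad = offsets[(offsets < lo) | (offsets > hi)].iloc[0]
        raise ValueError(f"offset {bad} outside model window [{lo}, {hi}]")
    index = pd.Index(range(lo, hi + 1), name="offset")
    counts = offsets.value_counts().reindex(index, fill_value=0).astype(int)
    profile, _ = average_information(model)
    if offsets.nunique() < 3:
        return PositionSpectrum(counts=counts, correlation=None)
    r, _p = stats.pearsonr(counts.to_numpy(dtype=float), profile)
    if not math.isfinite(r):
        return PositionSpectrum(counts=counts, correlation=None)
    return PositionSpectrum(counts=counts, correlation=float(r))


CONCORDANCE_LABELS = ("concordant", "partially_concordant", "discordant", "uninformative")

#: Observed-outcome vocabulary for concordance scoring.
OBSERVED_OUTCOMES = (
    "complete_loss",
    "residual_splicing",
    "normal_splicing",
    "increased_wildtype",
    "cryptic_splicing",
    "aberrant_splicing",
)


def _score_concordance_record(rec: dict) -> tuple[str, str]:
    predicted = rec.get("predicted")
    observed = rec.get("observed")
    if not predicted or not isinstance(predicted, str):
        return "uninformative", "missing prediction"
    if not observed or not isinstance(observed, str):
        return "uninformative", "missing validation outcome"

    if predicted == "abolished":
        if observed == "complete_loss":
            return "concordant", "a"
        if observed == "residual_splicing" and rec.get("rtpcr_heterozygote"):
            return "concordant", "a (heterozygote RT-PCR exception)"
        return "discordant", "a"
    if predicted == "leaky":
        if observed == "residual_splicing":
            return "concordant", "b"
        if observed == "cryptic_splicing" and rec.get("stronger_cryptic_activated"):
            return "concordant", "b (stronger cryptic exception)"
        return "discordant", "b"
    if predicted == "strengthened":
        if observed in ("normal_splicing", "increased_wildtype"):
            return "concordant", "c"
        return "discordant", "c"
    if predicted == "cryptic":
        if observed == "cryptic_splicing":
            if rec.get("predicted_top_isoform", True):
                return "concordant", "d"
            return "partially_concordant", "d (cryptic predicted but not top-ranked)"
        return "discordant", "d"
    if predicted == "regulatory":
        outcome = rec.get("binding_concordant")
        if outcome is None or (isinstance(outcome, float) and math.isnan(outcome)):
            return "uninformative", "e (no binding validation)"
        return ("concordant" if outcome else "discordant"), "e"
    if predicted == "neutral":
        if observed == "normal_splicing":
            return "concordant", "neutral"
        return "discordant", "neutral"
    return "uninformative", f"unknown prediction {predicted!r}"


@dataclass
class ConcordanceResult:
    table: pd.DataFrame
    percent_concordant: float | None
    n_informative: int
    n_concordant: int  # includes partially concordant, which met criterion d


def assess_concordance(records) -> ConcordanceResult:
    """Score predicted-vs-validated variant records.

    Each record carries a ``predicted`` class (abolished / leaky /
    strengthened / cryptic / regulatory / neutral), an ``observed`` outcome,
    and the optional qualifier flags the individual criteria reference.
    Records missing a required field are labelled uninformative and excluded
    from the denominator.  Partially concordant records (cryptic observed and
    predicted, but not ranked the predominant isoform) count toward the
    overall percent.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    rows = []
    for rec in records:
        label, criterion = _score_concordance_record(dict(rec))
        row = dict(rec)
        row["label"] = label
        row["criterion"] = criterion
        rows.append(row)
    table = pd.DataFrame(rows)
    informative = table[table["label"] != "uninformative"] if len(table) else table
    n_inf = len(informative)
    n_con = int((informative["label"].isin(["concordant", "partially_concordant"])).sum()) if n_inf else 0
    pct = 100.0 * n_con / n_inf if n_inf else None
    return ConcordanceResult(table=table, percent_concordant=pct,
                             n_informative=n_inf, n_concordant=n_con)
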