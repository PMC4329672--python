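"""Synthetic training sites, toy genes, and engineered variant panels.

Everything the toolkit needs for testing is generated here, with no
external downloads: binding-site samples drawn from stated frequency
matrices, toy genes with planted donor/acceptor sites of chosen strength,
and variant panels engineered by weight arithmetic to realize specific
molecular effects (site abolition, leaky splicing, the three cryptic
activation types, and neutral changes).

The bundled donor/acceptor/branch-point frequency matrices emulate the
composition of human constitutive splice sites: a near-invariant GT donor
dinucleotide with the characteristic exonic AG and intronic RAGT extension
(about 8 bits of total information), a pyrimidine-tract-plus-AG acceptor
(about 9.7 bits), and a degenerate yUnAy-like branch-point motif with a
conserved branch adenosine.  They are stylized — real genome-wide models
carry position correlations and lower-information tails that these tables
do not.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .infomodel import BASE_INDEX, BASES, InfoModel, model_from_frequencies
from .scoring import scan, score_site
from .variants import NaturalSite, VariantRecord

logger = logging.getLogger(__name__)

# Base order: A, C, G, T ----------------------------------------------------

DONOR_OFFSET_START = -3
DONOR_FREQUENCIES = np.array(
    [
        [0.33, 0.36, 0.19, 0.12],  # -3
        [0.61, 0.13, 0.12, 0.14],  # -2
        [0.10, 0.03, 0.80, 0.07],  # -1  (last exonic base)
        [0.001, 0.001, 0.997, 0.001],  # 0  first intronic base (G of GT)
        [0.002, 0.002, 0.001, 0.995],  # +1 (T of GT)
        [0.62, 0.02, 0.33, 0.03],  # +2
        [0.68, 0.09, 0.12, 0.11],  # +3
        [0.09, 0.02, 0.84, 0.05],  # +4
        [0.15, 0.17, 0.18, 0.50],  # +5
        [0.22, 0.25, 0.23, 0.30],  # +6
    ]
)

ACCEPTOR_OFFSET_START = -25
ACCEPTOR_FREQUENCIES = np.array(
    # distal pyrimidine region (-25..-19)
    [[0.20, 0.26, 0.17, 0.37]] * 7
    # core polypyrimidine tract (-18..-6)
    + [[0.10, 0.31, 0.12, 0.47]] * 13
    + [
        [0.07, 0.34, 0.09, 0.50],  # -5
        [0.24, 0.29, 0.21, 0.26],  # -4
        [0.06, 0.41, 0.07, 0.46],  # -3
        [0.06, 0.65, 0.01, 0.28],  # -2
        [0.997, 0.001, 0.001, 0.001],  # -1 (A of AG)
        [0.001, 0.001, 0.997, 0.001],  # 0  last intronic base (G of AG)
        [0.25, 0.14, 0.49, 0.12],  # +1 (first exonic base)
        [0.26, 0.26, 0.24, 0.24],  # +2
    ]
)

BRANCHPOINT_OFFSET_START = -5
BRANCHPOINT_FREQUENCIES = np.array(
    [
        [0.12, 0.36, 0.12, 0.40],  # -5
        [0.25, 0.25, 0.25, 0.25],  # -4
        [0.11, 0.40, 0.11, 0.38],  # -3
        [0.18, 0.15, 0.12, 0.55],  # -2
        [0.35, 0.10, 0.40, 0.15],  # -1
        [0.97, 0.01, 0.01, 0.01],  # 0  branch adenosine
        [0.12, 0.45, 0.13, 0.30],  # +1
    ]
)


def donor_model(name: str = "donor") -> InfoModel:
    return model_from_frequencies(DONOR_FREQUENCIES, DONOR_OFFSET_START,
                                  name=name, site_kind="donor")


def acceptor_model(name: str = "acceptor") -> InfoModel:
    return model_from_frequencies(ACCEPTOR_FREQUENCIES, ACCEPTOR_OFFSET_START,
                                  name=name, site_kind="acceptor")


def branchpoint_model(name: str = "BPS") -> InfoModel:
    return model_from_frequencies(BRANCHPOINT_FREQUENCIES, BRANCHPOINT_OFFSET_START,
                                  name=name, site_kind="branchpoint")


def default_models() -> dict[str, InfoModel]:
    return {"donor": donor_model(), "acceptor": acceptor_model(),
            "branchpoint": branchpoint_model()}


# ---------------------------------------------------------------------------
# Sampling training sites
# ---------------------------------------------------------------------------


def sample_sites(frequencies, n: int, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> list[str]:
    """Draw ``n`` site sequences independently per position.

    ``frequencies`` is an (L, 4) matrix whose rows sum to 1 (base order
    A, C, G, T).  Reproducible for a given seed.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.ndim != 2 or freqs.shape[1] != 4:
        raise ValueError("frequency matrix must have shape (length, 4)")
    if (freqs < 0).any() or not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of the frequency matrix must be probabilities summing to 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    if rng is None:
        rng = np.random.default_rng(seed)
    L = freqs.shape[0]
    cum = np.cumsum(freqs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n, L))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    letters = np.array(list(BASES))
    return ["".join(row) for row in letters[idx]]


def random_background(length: int, rng: np.random.Generator,
                      gc_bias: float = 0.5) -> str:
    """Uniform (or GC-biased) random sequence; higher GC raises the density
    of decoy splice-site-like sequence."""
    p_gc = gc_bias / 2.0
    p_at = (1.0 - gc_bias) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])
    letters = np.array(list(BASES))
    return "".join(letters[rng.choice(4, size=length, p=probs)])


# ---------------------------------------------------------------------------
# Site design by weight arithmetic
# ---------------------------------------------------------------------------


def design_site_sequence(
    model: InfoModel,
    target_ri: float,
    tolerance: float = 0.5,
    pinned: dict[int, str] | None = None,
    forbidden: dict[int, str] | None = None,
) -> str:
    """A window sequence whose R_i is within ``tolerance`` of ``target_ri``.

    Starts from the consensus and greedily substitutes single bases, always
    choosing the replacement that moves the score closest to the target
    without undershooting the tolerance band.  ``pinned`` fixes bases at
    given offsets (they are set first and never touched); ``forbidden`` maps
    offsets to bases the design must never introduce (e.g. no G upstream of
    an acceptor's AG, mimicking the AG-exclusion zone of real 3' splice
    sites, so that no shifted placement acquires its own AG).
    """
    if target_ri > model.max_score() + 1e-9:
        raise ValueError(
            f"target {target_ri} bits exceeds the model maximum "
            f"{model.max_score():.3f} bits"
        )
    window = list(model.consensus())
    pinned = pinned or {}
    forbidden = forbidden or {}
    banned = {model.position_index(o): set(b.upper()) for o, b in forbidden.items()}
    for offset, base in pinned.items():
        window[model.position_index(offset)] = base.upper()
    pinned_idx = {model.position_index(o) for o in pinned}
    score = model.score_window("".join(window))

    for _ in range(10 * model.length):
        if abs(score - target_ri) <= tolerance:
            break
        best = None
        for i in range(model.length):
            if i in pinned_idx:
                continue
            current = model.weights[i, BASE_INDEX[window[i]]]
            for j, b in enumerate(BASES):
                if b == window[i] or b in banned.get(i, ()):
                    continue
                new_score = score - current + model.weights[i, j]
                if new_score < target_ri - tolerance and score > target_ri:
                    continue  # would overshoot downward
                gain = abs(new_score - target_ri)
                if gain < abs(score - target_ri) - 1e-12:
                    if best is None or gain < best[0]:
                        best = (gain, i, j, new_score)
        if best is None:
            break
        _, i, j, score = best
        window[i] = BASES[j]
    final = model.score_window("".join(window))
    if abs(final - target_ri) > tolerance:
        raise ValueError(
            f"could not reach {target_ri} +/- {tolerance} bits "
            f"(best {final:.3f}, model max {model.max_score():.3f})"
        )
    return "".join(window)


# ---------------------------------------------------------------------------
# Toy genes
# ---------------------------------------------------------------------------


@dataclass
class PlantedSite:
    site_kind: str
    zero_coord: int  # 0-based
    strand: str
    r_i: float

    def as_natural(self, name: str = "") -> NaturalSite:
        return NaturalSite(site_kind=self.site_kind, zero_coord=self.zero_coord,
                           strand=self.strand, name=name)


@dataclass
class Scaffold:
    """A latent site planted to make one engineered effect possible."""

    effect: str  # 'type1', 'type2', 'type3'
    site_kind: str
    zero_coord: int  # decoy zero point, 0-based
    natural_index: int  # index into ToyGene.naturals of the cognate natural site
    variant_pos0: int | None = None  # suggested substitution (0-based), if any
    variant_alt: str | None = None


@dataclass
class ToyGene:
    seq_id: str
    sequence: str
    exons: list[tuple[int, int]]  # 1-based inclusive
    naturals: list[PlantedSite]
    scaffolds: dict[str, Scaffold]
    seed: int

    def natural_sites(self) -> list[NaturalSite]:
        return [p.as_natural(f"{p.site_kind}_{i}") for i, p in enumerate(self.naturals)]


def _plant(sequence: list[str], model: InfoModel, zero: int, window: str) -> None:
    start = zero + model.offset_start
    sequence[start : start + model.length] = list(window)


DEFAULT_SITE_TARGETS = {"donor": 8.0, "acceptor": 9.5}

#: Invariant core dinucleotides kept intact when designing natural sites:
#: GT at donor offsets 0/+1, AG at acceptor offsets -1/0.
CORE_PINS = {
    "donor": {0: "G", 1: "T"},
    "acceptor": {-1: "A", 0: "G"},
}


def make_toy_gene(
    n_exons: int = 3,
    exon_lengths=None,
    intron_lengths=None,
    site_strength_targets: dict[str, float] | None = None,
    models: dict[str, InfoModel] | None = None,
    seed: int = 1,
    *,
    r_i_min: float = 1.6,
    gc_bias: float = 0.5,
    plant_scaffolds: bool = True,
    seq_id: str = "toygene",
    max_attempts: int = 64,
) -> ToyGene:
    """A random gene with planted splice sites of chosen strength.

    Layout: intron0 | exon1 | intron1 | ... | exonN | intronN, so every exon
    carries both an acceptor and a donor.  Planted site strengths land
    within +/- 0.5 bits of the targets (about 8 bits for donors, the
    average strength of human donor sites; 9.5 for acceptors).  The
    background is resampled (up to ``max_attempts`` times) if any
    non-planted placement within 100 nt of a natural site reaches
    ``r_i_min``, which keeps the ground truth of engineered variant panels
    unambiguous.

    With ``plant_scaffolds`` three latent donor-type decoys are embedded so
    the panel generator can realize the cryptic activation types: a
    knocked-out strong site deep in an intron (Type 1), an overlapping
    decoy sharing the footprint of a natural donor (Type 2), and a
    pre-existing strong decoy downstream of a natural donor (Type 3).
    """
    models = models or default_models()
    targets = dict(DEFAULT_SITE_TARGETS)
    if site_strength_targets:
        targets.update(site_strength_targets)
    for kind in ("donor", "acceptor"):
        if targets[kind] > models[kind].max_score():
            raise ValueError(
                f"target {targets[kind]} bits unreachable: {kind} model maximum is "
                f"{models[kind].max_score():.3f} bits"
            )
    if exon_lengths is None:
        exon_lengths = [120] * n_exons
    if intron_lengths is None:
        intron_lengths = [300] * (n_exons + 1)
    if len(exon_lengths) != n_exons or len(intron_lengths) != n_exons + 1:
        raise ValueError("need n_exons exon lengths and n_exons + 1 intron lengths")
    if min(intron_lengths) < 120 or min(exon_lengths) < 40:
        raise ValueError("introns must be >= 120 nt and exons >= 40 nt for planting")

    donor = models["donor"]
    acceptor = models["acceptor"]

    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        total = sum(exon_lengths) + sum(intron_lengths)
        seq = list(random_background(total, rng, gc_bias))

        exons: list[tuple[int, int]] = []
        naturals: list[PlantedSite] = []
        pos = 0
        for i in range(n_exons):
            pos += intron_lengths[i]
            estart0, eend0 = pos, pos + exon_lengths[i] - 1
            exons.append((estart0 + 1, eend0 + 1))
            acc_zero = estart0 - 1
            don_zero = eend0 + 1
            acc_window = design_site_sequence(
                acceptor, targets["acceptor"], pinned=CORE_PINS["acceptor"],
                forbidden={**{off: "G" for off in range(-25, -1)}, 2: "G"})
            _plant(seq, acceptor, acc_zero, acc_window)
            naturals.append(PlantedSite("acceptor", acc_zero, "+", acceptor.score_window(acc_window)))
            pinned = dict(CORE_PINS["donor"])
            if plant_scaffolds and i == min(1, n_exons - 1):
                pinned[5] = "T"
            don_window = design_site_sequence(donor, targets["donor"], pinned=pinned)
            _plant(seq, donor, don_zero, don_window)
            naturals.append(PlantedSite("donor", don_zero, "+", donor.score_window(don_window)))
            pos = eend0 + 1

        scaffolds: dict[str, Scaffold] = {}
        if plant_scaffolds:
            donor_indices = [k for k, p in enumerate(naturals) if p.site_kind == "donor"]
            # Type 1: strong donor deep in the first intron-after-a-donor,
            # knocked out at +1 (T -> A); the restoring substitution creates it.
            d1 = naturals[donor_indices[0]]
            z1 = d1.zero_coord + 60
            strong = design_site_sequence(donor, targets["donor"],
                                          pinned=CORE_PINS["donor"])
            knocked = strong[: donor.position_index(1)] + "A" + strong[donor.position_index(1) + 1 :]
            _plant(seq, donor, z1, knocked)
            scaffolds["type1"] = Scaffold(
                effect="type1", site_kind="donor", zero_coord=z1,
                natural_index=donor_indices[0], variant_pos0=z1 + 1, variant_alt="T",
            )
            # Type 2: decoy overlapping the second natural donor, zero point
            # 5 nt downstream; completing its GT with the T->G substitution
            # at natural offset +5 weakens the natural site simultaneously.
            d2 = naturals[donor_indices[min(1, len(donor_indices) - 1)]]
            z2 = d2.zero_coord + 5
            completion = "AAGTT"  # decoy offsets +2..+6 (consensus-like)
            start = z2 + 2
            seq[start : start + 5] = list(completion)
            scaffolds["type2"] = Scaffold(
                effect="type2", site_kind="donor", zero_coord=z2,
                natural_index=donor_indices[min(1, len(donor_indices) - 1)],
                variant_pos0=z2, variant_alt="G",
            )
            # Type 3: full-strength pre-existing decoy 20 nt downstream of
            # the last natural donor (inside the default analysis window);
            # abolishing that donor activates it.
            d3 = naturals[donor_indices[-1]]
            z3 = d3.zero_coord + 20
            _plant(seq, donor, z3,
                   design_site_sequence(donor, targets["donor"], pinned=CORE_PINS["donor"]))
            scaffolds["type3"] = Scaffold(
                effect="type3", site_kind="donor", zero_coord=z3,
                natural_index=donor_indices[-1],
            )

        sequence = "".join(seq)
        if _background_is_clean(sequence, naturals, scaffolds, models, r_i_min):
            gene = ToyGene(seq_id=seq_id, sequence=sequence, exons=exons,
                           naturals=naturals, scaffolds=scaffolds, seed=seed)
            for p in gene.naturals:
                actual = score_site(models[p.site_kind], sequence, p.zero_coord).r_i
                p.r_i = actual
                if actual < r_i_min:
                    break
            else:
                return gene
    raise RuntimeError(
        f"could not generate a clean toy gene in {max_attempts} attempts (seed {seed})"
    )


def _background_is_clean(sequence, naturals, scaffolds, models, r_i_min,
                         guard_nt: int = 100) -> bool:
    """No accidental placement stronger than a planted natural site within
    guard_nt of it (decoy sites weaker than the naturals are expected — the
    genome is replete with them — and are left in place)."""
    allowed = {(p.site_kind, p.zero_coord) for p in naturals}
    allowed.update((s.site_kind, s.zero_coord) for s in scaffolds.values())
    for p in naturals:
        lo, hi = p.zero_coord - guard_nt, p.zero_coord + guard_nt + 1
        for hit in scan(models[p.site_kind], sequence, p.r_i, (max(lo, 0), hi)):
            if (p.site_kind, hit.zero_coord) not in allowed:
                return False
    return True


# ---------------------------------------------------------------------------
# Engineered variant panels
# ---------------------------------------------------------------------------


DEFAULT_PANEL_EFFECTS = (
    "abolish_natural",
    "leaky_natural",
    "neutral",
    "cryptic_type1",
    "cryptic_type2",
    "cryptic_type3",
)

EFFECT_LABELS = {
    "abolish_natural": "abolished",
    "leaky_natural": "leaky",
    "neutral": "neutral",
    "cryptic_type1": "type1",
    "cryptic_type2": "type2",
    "cryptic_type3": "type3",
}


@dataclass
class PanelEntry:
    variant: VariantRecord
    label: str
    effect: str
    target_coord: int | None  # 0-based zero point of the targeted site


def _substitution(gene: ToyGene, pos0: int, alt: str) -> VariantRecord:
    return VariantRecord(gene.seq_id, pos0 + 1, gene.sequence[pos0], alt)


def _competitive_thresholds(gene: ToyGene, slack_bits: float = 1.0) -> dict[str, float]:
    """Per-polarity strength above which a decoy competes with the natural
    sites for interpretation purposes."""
    out: dict[str, float] = {}
    for p in gene.naturals:
        thr = p.r_i - slack_bits
        out[p.site_kind] = min(out.get(p.site_kind, thr), thr)
    return out


def _side_effects(gene: ToyGene, pos0: int, alt: str, models,
                  thresholds: dict[str, float], significance_bits: float,
                  exclude: set[tuple[str, int]]) -> bool:
    """Would the substitution disturb any non-excluded placement in a way
    that could change the variant's interpretation?

    True when some placement crosses its polarity's competitive threshold
    upward, or moves by at least the significance threshold while at
    competitive strength on either side of the change.  Sub-competitive
    decoy churn is ignored — it cannot produce a reportable activation
    event.  Checked by rescanning the edited neighbourhood.
    """
    mutated = gene.sequence[:pos0] + alt + gene.sequence[pos0 + 1 :]
    for model in models.values():
        thr = thresholds.get(model.site_kind)
        if thr is None:
            continue
        lo, hi = pos0 - model.length, pos0 + model.length + 1
        pre = {s.zero_coord: s.r_i for s in scan(model, gene.sequence, -1e9, (lo, hi))}
        post = {s.zero_coord: s.r_i for s in scan(model, mutated, -1e9, (lo, hi))}
        for z, r_post in post.items():
            if (model.site_kind, z) in exclude:
                continue
            r_pre = pre.get(z, -1e9)
            if r_pre < thr <= r_post:
                return True
            if abs(r_post - r_pre) >= significance_bits and max(r_pre, r_post) >= thr:
                return True
    return False


def _has_nearby_decoy(gene: ToyGene, natural: PlantedSite, model,
                      slack_bits: float = 1.0, reach: int = 60) -> bool:
    """Is there a pre-existing same-polarity decoy competitive with a natural
    site (within slack_bits of its strength) nearby?  Variants at such sites
    cannot be given an unambiguous abolished/leaky ground-truth label (the
    decoy could be typed as an activated cryptic site)."""
    lo = max(0, natural.zero_coord - reach)
    hi = natural.zero_coord + reach + 1
    for hit in scan(model, gene.sequence, natural.r_i - slack_bits, (lo, hi)):
        if hit.zero_coord != natural.zero_coord:
            return True
    return False


def _natural_substitution(gene: ToyGene, natural: PlantedSite, model: InfoModel,
                          models, r_i_min: float, lo: float, hi: float,
                          *, significance_bits: float = 1.0,
                          keep_above_min: bool | None = None,
                          avoid_offsets=()) -> tuple[int, str] | None:
    """Find a substitution in a natural-site window with delta_ri in [lo, hi].

    Candidates are ranked by distance from the band centre; ones whose side
    effects could change the interpretation (an unintended site crossing
    r_i_min or a significant move of a functional placement) are rejected.
    """
    centre = (lo + hi) / 2.0
    exclude = {(p.site_kind, p.zero_coord) for p in gene.naturals}
    exclude.update((s.site_kind, s.zero_coord) for s in gene.scaffolds.values())
    candidates = []
    for offset in model.offsets:
        if offset in avoid_offsets:
            continue
        pos0 = natural.zero_coord + int(offset)
        ref = gene.sequence[pos0]
        for alt in BASES:
            if alt == ref:
                continue
            delta = model.weight(alt, int(offset)) - model.weight(ref, int(offset))
            if not lo <= delta <= hi:
                continue
            final = natural.r_i + delta
            if keep_above_min is True and final < r_i_min + 0.5:
                continue
            if keep_above_min is False and final >= r_i_min - 0.5:
                continue
            candidates.append((abs(delta - centre), pos0, alt))
    thresholds = _competitive_thresholds(gene)
    for _, pos0, alt in sorted(candidates):
        if not _side_effects(gene, pos0, alt, models, thresholds, significance_bits, exclude):
            return pos0, alt
    return None


def make_variant_panel(
    gene: ToyGene,
    effects=DEFAULT_PANEL_EFFECTS,
    models: dict[str, InfoModel] | None = None,
    seed: int = 1,
    *,
    r_i_min: float = 1.6,
    significance_bits: float = 1.0,
) -> list[PanelEntry]:
    """Engineer one variant per intended effect, with ground-truth labels.

    Substitutions are chosen by weight arithmetic on the planted sites (and
    the gene's latent scaffolds for the cryptic types); a candidate whose
    side effect would create an unintended site above ``r_i_min`` is
    rejected.  Effects that cannot be realized on this gene are skipped
    with a logged notice.
    """
    models = models or default_models()
    donor = models["donor"]
    acceptor = models["acceptor"]
    rng = np.random.default_rng(seed)
    entries: list[PanelEntry] = []
    donor_sites = [p for p in gene.naturals if p.site_kind == "donor"]
    acceptor_sites = [p for p in gene.naturals if p.site_kind == "acceptor"]
    scaffold_coords = {(s.site_kind, s.zero_coord) for s in gene.scaffolds.values()}

    for effect in effects:
        entry = None
        if effect == "abolish_natural":
            # prefer donors without any functional decoy of the same polarity
            # nearby, so abolition cannot be read as cryptic activation
            candidates = [p for p in donor_sites
                          if not _has_nearby_decoy(gene, p, donor)]
            for site in candidates:
                found = _natural_substitution(
                    gene, site, donor, models, r_i_min,
                    significance_bits=significance_bits,
                    lo=-30.0, hi=-7.0 - significance_bits, keep_above_min=False)
                if found:
                    entry = PanelEntry(_substitution(gene, *found), "abolished",
                                       effect, site.zero_coord)
                    break
        elif effect == "leaky_natural":
            candidates = [p for p in acceptor_sites
                          if not _has_nearby_decoy(gene, p, acceptor)]
            for site in candidates:
                found = _natural_substitution(
                    gene, site, acceptor, models, r_i_min,
                    significance_bits=significance_bits,
                    lo=-3.8, hi=-1.3, keep_above_min=True)
                if found:
                    entry = PanelEntry(_substitution(gene, *found), "leaky",
                                       effect, site.zero_coord)
                    break
        elif effect == "neutral":
            entry = _neutral_variant(gene, models, r_i_min, significance_bits, rng)
        elif effect in ("cryptic_type1", "cryptic_type2", "cryptic_type3"):
            entry = _cryptic_variant(gene, effect.removeprefix("cryptic_"), models,
                                     r_i_min, significance_bits)
        else:
            raise ValueError(f"unknown effect {effect!r}")
        if entry is None:
            logger.warning("effect %s not achievable on this gene; skipped", effect)
        else:
            entries.append(entry)
    return entries


def _neutral_variant(gene, models, r_i_min, significance_bits, rng):
    """A mid-exon substitution that disturbs no functional placement: every
    overlapping site moves by less than the significance threshold or stays
    below competitive strength throughout."""
    thresholds = _competitive_thresholds(gene)
    for estart1, eend1 in gene.exons:
        mid0 = (estart1 - 1 + eend1 - 1) // 2
        for shift in range(0, 20):
            for pos0 in (mid0 + shift, mid0 - shift):
                ref = gene.sequence[pos0]
                for alt in BASES:
                    if alt == ref:
                        continue
                    if not _side_effects(gene, pos0, alt, models, thresholds,
                                         significance_bits, set()):
                        return PanelEntry(_substitution(gene, pos0, alt),
                                          "neutral", "neutral", None)
    return None


def _cryptic_variant(gene, type_name, models, r_i_min, significance_bits):
    scaffold = gene.scaffolds.get(type_name)
    if scaffold is None:
        return None
    donor = models[scaffold.site_kind]
    natural = gene.naturals[scaffold.natural_index]
    if type_name in ("type1", "type2"):
        pos0, alt = scaffold.variant_pos0, scaffold.variant_alt
        if gene.sequence[pos0] == alt:
            return None
        return PanelEntry(_substitution(gene, pos0, alt), EFFECT_LABELS[f"cryptic_{type_name}"],
                          f"cryptic_{type_name}", scaffold.zero_coord)
    # type3: abolish the cognate natural donor while the decoy is untouched
    decoy_span = (scaffold.zero_coord + donor.offset_start,
                  scaffold.zero_coord + donor.offset_end)
    avoid = [off for off in donor.offsets
             if decoy_span[0] <= natural.zero_coord + int(off) <= decoy_span[1]]
    found = _natural_substitution(
        gene, natural, donor, models, r_i_min,
        significance_bits=significance_bits,
        lo=-30.0, hi=-7.0 - significance_bits, keep_above_min=False,
        avoid_offsets=avoid)
    if not found:
        return None
    return PanelEntry(_substitution(gene, *found), "type3", "cryptic_type3",
                      scaffold.zero_coord)
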