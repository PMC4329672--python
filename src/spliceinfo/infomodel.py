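"""Individual-information models of nucleic-acid binding sites.

An information weight matrix ("ribl") stores, for each position ``l`` of a
binding-site window and each base ``b``, the weight

    w(b, l) = 2 + log2 f(b, l)        [bits]

where ``f(b, l)`` is the frequency of base ``b`` among aligned functional
sites.  The individual information ``R_i`` of one candidate sequence is the
sum of the weights of its bases (a dot product with the one-hot encoding),
and the mean over the training set, ``R_sequence``, measures the overall
conservation of the binding site.  With no pseudocount and no small-sample
correction, ``R_sequence`` equals the sum over positions of ``2 - H(l)``
where ``H(l)`` is the Shannon entropy of the base distribution at ``l``.

Window positions are numbered relative to the model's zero point, the
intron-side base adjacent to the splice junction: the first intronic base
for a donor (default window [-3, +6]) and the last intronic base for an
acceptor (default window [-25, +2]).  Zero is a real position; no offset is
skipped.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
SITE_KINDS = ("donor", "acceptor", "branchpoint", "regulatory")

#: Finite stand-in for log2(0): weight given to a base never observed in
#: training when the pseudocount is zero.  Keeps R_i finite while making a
#: forbidden base catastrophic for the score.
DEFAULT_FLOOR = -20.0


def _clean_sequence(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


@dataclass
class InfoModel:
    """A per-position, per-base information weight matrix in bits."""

    name: str
    site_kind: str
    offset_start: int
    offset_end: int
    weights: np.ndarray  # shape (window length, 4), base order A C G T
    n_sites: int = 0
    r_sequence: float = 0.0
    r_sequence_sd: float = 0.0
    pseudocount: float = 0.0
    correction_applied: bool = False
    floor: float = DEFAULT_FLOOR
    #: exact base frequencies, kept when the model is built in-process;
    #: derived from the weights (floor -> 0) otherwise
    frequencies_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.site_kind not in SITE_KINDS:
            raise ValueError(f"unknown site kind {self.site_kind!r}; expected one of {SITE_KINDS}")
        expected = self.offset_end - self.offset_start + 1
        if self.weights.shape != (expected, 4):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match window "
                f"[{self.offset_start}, {self.offset_end}] ({expected} positions x 4 bases)"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def length(self) -> int:
        return self.offset_end - self.offset_start + 1

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.offset_start, self.offset_end + 1)

    def position_index(self, offset: int) -> int:
        if not self.offset_start <= offset <= self.offset_end:
            raise ValueError(
                f"offset {offset} outside model window [{self.offset_start}, {self.offset_end}]"
            )
        return offset - self.offset_start

    def weight(self, base: str, offset: int) -> float:
        """Weight in bits of ``base`` at window ``offset``."""
        base = _clean_sequence(base)
        if base not in BASE_INDEX:
            raise ValueError(f"invalid base {base!r}")
        return float(self.weights[self.position_index(offset), BASE_INDEX[base]])

    # -- derived quantities ---------------------------------------------

    def frequencies(self) -> np.ndarray:
        """Base frequencies at each position.

        Uses the exact matrix recorded at build time when available;
        otherwise inverts f = 2^(w-2), treating floor weights as zero.
        """
        if self.frequencies_matrix is not None:
            return self.frequencies_matrix
        f = np.power(2.0, self.weights - 2.0)
        f[self.weights <= self.floor + 1e-9] = 0.0
        return f / f.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.weights, axis=1))

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def score_window(self, window: str) -> float:
        """R_i of a window sequence exactly the model length (no N handling)."""
        window = _clean_sequence(window)
        if len(window) != self.length:
            raise ValueError(f"window length {len(window)} != model length {self.length}")
        idx = [BASE_INDEX[b] for b in window]
        return float(self.weights[np.arange(self.length), idx].sum())


def build_model(
    training_seqs,
    offset_start: int,
    offset_end: int,
    *,
    name: str = "model",
    site_kind: str = "donor",
    pseudocount: float = 0.0,
    apply_correction: bool = False,
    floor: float = DEFAULT_FLOOR,
) -> InfoModel:
    """Build an information weight matrix from aligned binding-site sequences.

    Parameters
    ----------
    training_seqs
        Equal-length nucleotide strings (A/C/G/T/U/N; U is mapped to T).
        Records containing N are dropped with a logged warning.
    offset_start, offset_end
        Inclusive window coordinates relative to the model zero point.
    pseudocount
        Added to every base count; frequencies are
        (count + pseudocount) / (n + 4 * pseudocount).
    apply_correction
        Subtract a first-order small-sample correction, 3 / (2 n ln 2) bits
        per position, from ``r_sequence``.  Individual weights are left
        untouched.
    floor
        Weight assigned to a base with zero frequency (pseudocount 0).
    """
    length = offset_end - offset_start + 1
    if length < 1:
        raise ValueError("offset_end must be >= offset_start")

    kept: list[str] = []
    n_dropped = 0
    for i, raw in enumerate(training_seqs):
        seq = _clean_sequence(raw)
        if len(seq) != length:
            raise ValueError(
                f"training record {i} has length {len(seq)}, expected window length {length}"
            )
        if "N" in seq:
            n_dropped += 1
            continue
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(f"training record {i} contains invalid characters {sorted(bad)}")
        kept.append(seq)
    if n_dropped:
        logger.warning("dropped %d training sequence(s) containing N", n_dropped)
    if not kept:
        raise ValueError("no usable training sequences (empty input or all dropped)")

    n = len(kept)
    counts = np.zeros((length, 4), dtype=float)
    encoded = np.array([[BASE_INDEX[b] for b in s] for s in kept])
    for j in range(4):
        counts[:, j] = (encoded == j).sum(axis=0)

    freqs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        weights = 2.0 + np.log2(freqs)
    weights[freqs == 0.0] = floor

    model = InfoModel(
        name=name,
        site_kind=site_kind,
        offset_start=offset_start,
        offset_end=offset_end,
        weights=weights,
        n_sites=n,
        pseudocount=pseudocount,
        correction_applied=apply_correction,
        floor=floor,
        frequencies_matrix=freqs,
    )
    ris = np.array([model.score_window(s) for s in kept])
    model.r_sequence = float(ris.mean())
    model.r_sequence_sd = float(ris.std(ddof=1)) if n > 1 else 0.0
    if apply_correction:
        model.r_sequence -= small_sample_correction(n, length)
    return model


def small_sample_correction(n: int, n_positions: int) -> float:
    """First-order sampling-bias correction e(n) in bits.

    Estimating entropy from n observations is biased low, which inflates the
    apparent information by approximately (K - 1) / (2 n ln 2) bits per
    position for a K-letter alphabet.
    """
    return n_positions * 3.0 / (2.0 * n * math.log(2.0))


def model_from_frequencies(
    frequencies,
    offset_start: int,
    *,
    name: str = "model",
    site_kind: str = "donor",
    n_sites: int = 0,
    floor: float = DEFAULT_FLOOR,
) -> InfoModel:
    """Construct a model directly from a per-position base-frequency matrix.

    ``r_sequence`` and its SD are the analytic mean and standard deviation of
    R_i under the generating distribution (independent positions).
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.ndim != 2 or freqs.shape[1] != 4:
        raise ValueError("frequency matrix must have shape (length, 4)")
    if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("frequencies at each position must sum to 1")
    if (freqs < 0).any():
        raise ValueError("frequencies must be non-negative")
    with np.errstate(divide="ignore"):
        weights = 2.0 + np.log2(freqs)
    weights[freqs == 0.0] = floor

    mean_per_pos = np.where(freqs > 0, freqs * weights, 0.0).sum(axis=1)
    second_moment = np.where(freqs > 0, freqs * weights**2, 0.0).sum(axis=1)
    var = float((second_moment - mean_per_pos**2).sum())

    model = InfoModel(
        name=name,
        site_kind=site_kind,
        offset_start=offset_start,
        offset_end=offset_start + freqs.shape[0] - 1,
        weights=weights,
        n_sites=n_sites,
        r_sequence=float(mean_per_pos.sum()),
        r_sequence_sd=math.sqrt(max(var, 0.0)),
        pseudocount=0.0,
        floor=floor,
        frequencies_matrix=freqs,
    )
    return model


def average_information(model: InfoModel) -> tuple[np.ndarray, float]:
    """Per-position information profile 2 - H(l) and its sum.

    The sum equals ``model.r_sequence`` exactly when the model was built with
    pseudocount 0 and no small-sample correction.
    """
    freqs = model.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -terms.sum(axis=1)
    profile = 2.0 - entropy
    return profile, float(profile.sum())


def export_logo_data(model: InfoModel) -> pd.DataFrame:
    """Per-position base heights for a sequence logo.

    Height of base b at position l is f(b, l) x (2 - H(l)), so the stack at
    each position sums to that position's contribution to the average
    information.  Bases are ranked by descending frequency within each
    position.
    """
    freqs = model.frequencies()
    profile, _ = average_information(model)
    rows = []
    for i, offset in enumerate(model.offsets):
        order = np.argsort(-freqs[i], kind="stable")
        for rank, j in enumerate(order):
            rows.append(
                {
                    "offset": int(offset),
                    "base": BASES[j],
                    "frequency": float(freqs[i, j]),
                    "height": float(freqs[i, j] * profile[i]),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model file format: TSV of weights (one row per base, one column per offset)
# plus a JSON sidecar with the metadata.  Round-trips are exact on the
# decimal representation written (12 significant digits).
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_model(model: InfoModel, path) -> None:
    path = Path(path)
    offsets = model.offsets
    lines = ["offset\t" + "\t".join(str(int(o)) for o in offsets)]
    for j, base in enumerate(BASES):
        vals = "\t".join(format(model.weights[i, j], ".12g") for i in range(model.length))
        lines.append(f"{base}\t{vals}")
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "name": model.name,
        "site_kind": model.site_kind,
        "offset_start": model.offset_start,
        "offset_end": model.offset_end,
        "n_sites": model.n_sites,
        "r_sequence": model.r_sequence,
        "r_sequence_sd": model.r_sequence_sd,
        "pseudocount": model.pseudocount,
        "correction_applied": model.correction_applied,
        "floor": model.floor,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_model(path) -> InfoModel:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "offset":
        raise ValueError(f"{path}: expected header starting with 'offset'")
    offsets = [int(x) for x in header[1:]]
    weights = np.zeros((len(offsets), 4))
    for ln in lines[1:5]:
        fields = ln.split("\t")
        base = fields[0]
        if base not in BASE_INDEX:
            raise ValueError(f"{path}: unexpected base row {base!r}")
        weights[:, BASE_INDEX[base]] = [float(x) for x in fields[1:]]
    meta_path = _sidecar_path(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {}
    model = InfoModel(
        name=meta.get("name", path.stem),
        site_kind=meta.get("site_kind", "donor"),
        offset_start=meta.get("offset_start", offsets[0]),
        offset_end=meta.get("offset_end", offsets[-1]),
        weights=weights,
        n_sites=meta.get("n_sites", 0),
        r_sequence=meta.get("r_sequence", 0.0),
        r_sequence_sd=meta.get("r_sequence_sd", 0.0),
        pseudocount=meta.get("pseudocount", 0.0),
        correction_applied=meta.get("correction_applied", False),
        floor=meta.get("floor", DEFAULT_FLOOR),
    )
    if offsets != list(range(model.offset_start, model.offset_end + 1)):
        raise ValueError(f"{path}: offset columns are not contiguous")
    return model
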