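"""Positional base-frequency models of donor and acceptor splice sites.

Two scoring schemes are exposed for a trained model:

* **consensus value (CV)** -- a Shapiro & Senapathy style percent score,
  normalised between the worst- and best-possible window sequence::

      cv = 100 * (sum_i f(b_i, i) - sum_i min_b f(b, i))
               / (sum_i max_b f(b, i) - sum_i min_b f(b, i))

  so the per-position-argmax sequence scores exactly 100 and the argmin
  sequence exactly 0.

* **individual information (Ri, bits)** -- the information-theoretic site
  strength ``Ri = sum_i (2 + log2 f(b_i, i))``, additive over positions; a
  uniform model yields 0 bits for any window and a 1-bit change corresponds
  to a 2-fold change in predicted spliceosome binding affinity.  The
  small-sample correction term of the classical formulation is omitted (a
  documented simplification; with a positive pseudocount Ri is always
  finite).

Windows are anchored on the nearly invariant GT/AG intron ends.  Default
geometry: donor = last 3 exonic + first 6 intronic bases (-3..+6), acceptor
= last 12 intronic + first 2 exonic bases (-12..+2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR = "donor"
ACCEPTOR = "acceptor"

#: default detection floors, one per scorer scale
DEFAULT_CV_FLOOR = 70.0
DEFAULT_RI_FLOOR = 0.0
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class SiteWindow:
    """Geometry of a splice-site window around the exon/intron junction."""

    site_type: str
    exonic: int
    intronic: int

    def __post_init__(self) -> None:
        if self.site_type not in (DONOR, ACCEPTOR):
            raise ValueError(f"site_type must be donor or acceptor, got {self.site_type!r}")
        if self.exonic < 0 or self.intronic < 0:
            raise ValueError("window spans must be nonnegative")
        if self.length < 2:
            raise ValueError("window must span at least 2 positions")
        if self.intronic < 2:
            raise ValueError("window must cover the invariant GT/AG dinucleotide")

    @property
    def length(self) -> int:
        return self.exonic + self.intronic

    def window_start(self, junction: int) -> int:
        """Gene-local start of the window for a junction coordinate.

        Donor junctions index the first intronic base; acceptor junctions
        index the first exonic base (i.e. one past the last intronic base).
        """
        if self.site_type == DONOR:
            return junction - self.exonic
        return junction - self.intronic

    def junction_from_start(self, start: int) -> int:
        if self.site_type == DONOR:
            return start + self.exonic
        return start + self.intronic

    def invariant_slice(self) -> tuple[int, str]:
        """(offset within window, expected dinucleotide) for GT / AG."""
        if self.site_type == DONOR:
            return self.exonic, "GT"
        return self.intronic - 2, "AG"


DONOR_WINDOW = SiteWindow(DONOR, exonic=3, intronic=6)
ACCEPTOR_WINDOW = SiteWindow(ACCEPTOR, exonic=2, intronic=12)


@dataclass(frozen=True)
class ScoredSite:
    """A candidate splice junction with its scores."""

    position: int
    site_type: str
    cv: float
    ri: float | None

    def score(self, scorer: str) -> float:
        if scorer == "cv":
            return self.cv
        if scorer == "ri":
            if self.ri is None:
                raise ValueError("ri not available (zero frequencies in model)")
            return self.ri
        raise ValueError(f"unknown scorer {scorer!r}")


def _encode(seq: str, context: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT symbol {exc.args[0]!r} in {context}") from None


def frequency_matrix(
    training_windows: list[str], length: int, pseudocount: float
) -> np.ndarray:
    """Positional base counts -> smoothed frequencies, shape (length, 4).

    ``freqs[i][b] = (count(b at i) + pseudocount) / (n + 4 * pseudocount)``.
    """
    if not training_windows:
        raise ValueError("empty training set")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    n = len(training_windows)
    counts = np.zeros((length, 4), dtype=float)
    for k, w in enumerate(training_windows):
        if len(w) != length:
            raise ValueError(
                f"training window {k} has length {len(w)}, expected {length}"
            )
        idx = _encode(w, f"training window {k}")
        counts[np.arange(length), idx] += 1.0
    return (counts + pseudocount) / (n + 4.0 * pseudocount)


def cv_from_freqs(freqs: np.ndarray, window_seq: str) -> float:
    """Consensus value (%) of a window under a raw frequency matrix."""
    idx = _encode(window_seq, "window sequence")
    if len(idx) != len(freqs):
        raise ValueError(f"window length {len(idx)} != matrix length {len(freqs)}")
    s = freqs[np.arange(len(idx)), idx].sum()
    smin = freqs.min(axis=1).sum()
    smax = freqs.max(axis=1).sum()
    if smax - smin <= 0:
        raise ValueError("uninformative model: max and min window scores coincide")
    return float(100.0 * (s - smin) / (smax - smin))


def ri_from_freqs(freqs: np.ndarray, window_seq: str) -> float:
    """Individual information (bits) of a window under a frequency matrix."""
    idx = _encode(window_seq, "window sequence")
    if len(idx) != len(freqs):
        raise ValueError(f"window length {len(idx)} != matrix length {len(freqs)}")
    f = freqs[np.arange(len(idx)), idx]
    if np.any(f <= 0):
        raise ValueError(
            "zero frequency in model at an observed base; retrain with "
            "pseudocount > 0 to keep Ri finite"
        )
    return float(np.sum(2.0 + np.log2(f)))


class SpliceModel:
    """Trained positional base-frequency model for one site type."""

    def __init__(
        self,
        window: SiteWindow,
        freqs: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        n_training: int = 0,
    ) -> None:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (window.length, 4):
            raise ValueError(
                f"freqs shape {freqs.shape} does not match window length {window.length}"
            )
        if np.any(freqs < 0):
            raise ValueError("frequencies must be nonnegative")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("positional frequencies must each sum to 1")
        self.window = window
        self.freqs = freqs
        self.pseudocount = float(pseudocount)
        self.n_training = int(n_training)

    # -- scoring -----------------------------------------------------------

    def _check_len(self, window_seq: str) -> None:
        if len(window_seq) != self.window.length:
            raise ValueError(
                f"window sequence length {len(window_seq)} != model window "
                f"length {self.window.length}"
            )

    def consensus_value(self, window_seq: str) -> float:
        """Percent consensus value of a window sequence (0..100)."""
        self._check_len(window_seq)
        return cv_from_freqs(self.freqs, window_seq)

    def individual_information(self, window_seq: str) -> float:
        """Individual information Ri of a window sequence, in bits."""
        self._check_len(window_seq)
        return ri_from_freqs(self.freqs, window_seq)

    def score(self, window_seq: str, scorer: str) -> float:
        if scorer == "cv":
            return self.consensus_value(window_seq)
        if scorer == "ri":
            return self.individual_information(window_seq)
        raise ValueError(f"unknown scorer {scorer!r} (expected 'cv' or 'ri')")

    def score_junction(
        self, sequence: str, junction: int, scorer: str = "cv"
    ) -> float | None:
        """Score the window anchored at a gene-local junction.

        Returns None when the window does not fit inside the sequence.
        """
        start = self.window.window_start(junction)
        if start < 0 or start + self.window.length > len(sequence):
            return None
        return self.score(sequence[start : start + self.window.length], scorer)

    def max_score(self, scorer: str = "cv") -> float:
        """Best attainable score under this model."""
        if scorer == "cv":
            return 100.0
        f = self.freqs.max(axis=1)
        if np.any(f <= 0):
            raise ValueError("zero frequencies; Ri undefined")
        return float(np.sum(2.0 + np.log2(f)))

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"# site_type={self.window.site_type}\texonic={self.window.exonic}"
            f"\tintronic={self.window.intronic}"
            f"\tpseudocount={self.pseudocount!r}\tn_training={self.n_training}",
            "position\t" + "\t".join(BASES),
        ]
        for i, row in enumerate(self.freqs):
            lines.append(f"{i}\t" + "\t".join(f"{v:.10g}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpliceModel":
        text = Path(path).read_text().strip().splitlines()
        header = text[0]
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing model header line")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").split("\t") if "=" in item
        )
        window = SiteWindow(meta["site_type"], int(meta["exonic"]), int(meta["intronic"]))
        rows = [line.split("\t")[1:] for line in text[2:]]
        freqs = np.array(rows, dtype=float)
        return cls(
            window,
            freqs,
            pseudocount=float(meta.get("pseudocount", DEFAULT_PSEUDOCOUNT)),
            n_training=int(meta.get("n_training", 0)),
        )

    # -- sampling (used by the synthetic-gene generator) --------------------

    def sample_window(self, rng: np.random.Generator) -> str:
        """Draw one window sequence position-wise from the model frequencies.

        The invariant GT/AG dinucleotide is enforced exactly.
        """
        idx = [int(rng.choice(4, p=row / row.sum())) for row in self.freqs]
        chars = [BASES[i] for i in idx]
        off, dinuc = self.window.invariant_slice()
        chars[off : off + 2] = list(dinuc)
        return "".join(chars)


def build_model(
    training_windows: list[str],
    window: SiteWindow,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SpliceModel:
    """Train a positional frequency model from aligned window sequences.

    ``freqs[i][b] = (count(b at i) + pseudocount) / (n + 4 * pseudocount)``.
    """
    freqs = frequency_matrix(training_windows, window.length, pseudocount)
    return SpliceModel(
        window, freqs, pseudocount=pseudocount, n_training=len(training_windows)
    )


def scan_sites(
    model: SpliceModel,
    sequence: str,
    floor: float,
    scorer: str = "cv",
    region: tuple[int, int] | None = None,
) -> list[ScoredSite]:
    """Score every full window position and keep junctions scoring >= floor.

    ``region`` optionally restricts reported *junction* coordinates to
    ``[region[0], region[1])``; window positions that do not fit entirely
    inside the sequence are skipped.  Results are sorted by position.
    """
    L = model.window.length
    if len(sequence) <= L:
        raise ValueError(f"sequence length {len(sequence)} not longer than window {L}")
    idx = _encode(sequence, "sequence")
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    pos = np.arange(L)
    per_base = model.freqs[pos, windows]  # (n_windows, L)
    s = per_base.sum(axis=1)
    smin = model.freqs.min(axis=1).sum()
    smax = model.freqs.max(axis=1).sum()
    if smax - smin <= 0:
        raise ValueError("uninformative model: max and min window scores coincide")
    cv = 100.0 * (s - smin) / (smax - smin)
    if np.all(model.freqs > 0):
        ri = (2.0 + np.log2(per_base)).sum(axis=1)
    else:
        ri = None
    chosen = cv if scorer == "cv" else ri
    if chosen is None:
        raise ValueError("ri scanning requires a model with pseudocount > 0")

    out: list[ScoredSite] = []
    for start in np.nonzero(chosen >= floor)[0]:
        junction = model.window.junction_from_start(int(start))
        if region is not None and not (region[0] <= junction < region[1]):
            continue
        out.append(
            ScoredSite(
                position=junction,
                site_type=model.window.site_type,
                cv=float(cv[start]),
                ri=float(ri[start]) if ri is not None else None,
            )
        )
    return out
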