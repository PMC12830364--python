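"""Position weight matrix container.

A PWM is a 4 x w column-stochastic probability matrix over (A, C, G, T)
together with the order-0 background it is scored against and the
pseudocount used when it was estimated from counts. Scores are log-odds in
bits: sum over columns of log2(p_base / background_base).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sequence import ALPHABET, require_acgt

UNIFORM = np.full(4, 0.25)

#: default pseudocount added per base per column when estimating from counts
DEFAULT_PSEUDOCOUNT = 0.25


@dataclass(frozen=True)
class PWM:
    """Column-stochastic motif model over (A, C, G, T).

    Parameters
    ----------
    probs
        Array of shape (4, w); each column sums to 1.
    background
        Order-0 background frequencies, length 4.
    pseudocount
        Per-base pseudocount recorded from estimation (informational).
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("PWM probs must have shape (4, w)")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        *,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        num = counts + pseudocount
        denom = num.sum(axis=0)
        if (denom == 0).any():
            raise ValueError("empty column with zero pseudocount")
        bg = UNIFORM.copy() if background is None else np.asarray(background, float)
        return cls(num / denom, background=bg, pseudocount=pseudocount)

    @classmethod
    def from_sites(
        cls,
        sites: list[str],
        *,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        """Estimate from an ungapped alignment of equal-length ACGT strings."""
        if not sites:
            raise ValueError("need at least one site")
        w = len(sites[0])
        if any(len(s) != w for s in sites):
            raise ValueError("sites must all have equal length")
        counts = np.zeros((4, w))
        for s in sites:
            codes = require_acgt(s, what="site")
            counts[codes, np.arange(w)] += 1.0
        return cls.from_counts(counts, background=background, pseudocount=pseudocount)

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        *,
        match_prob: float = 0.7,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Soft point-mass PWM: match_prob on the consensus base, the rest
        spread evenly on the other three (the seed model for discovery)."""
        codes = require_acgt(consensus, what="consensus")
        w = codes.shape[0]
        probs = np.full((4, w), (1.0 - match_prob) / 3.0)
        probs[codes, np.arange(w)] = match_prob
        bg = UNIFORM.copy() if background is None else np.asarray(background, float)
        return cls(probs, background=bg, pseudocount=0.0)

    # -- derived quantities ----------------------------------------------

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    @property
    def logodds(self) -> np.ndarray:
        """log2(p / background), shape (4, w); -inf where p == 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background[:, None])

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information content 2 - H(column), bits, in [0, 2]."""
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.probs > 0, self.probs * np.log2(self.probs), 0.0)
        return 2.0 + plogp.sum(axis=0)

    def __eq__(self, other: object) -> bool:  # frozen dataclass w/ arrays
        if not isinstance(other, PWM):
            return NotImplemented
        return (
            np.array_equal(self.probs, other.probs)
            and np.array_equal(self.background, other.background)
            and self.pseudocount == other.pseudocount
        )

    def __hash__(self) -> int:
        return hash((self.probs.tobytes(), self.background.tobytes()))


def column_information(counts: np.ndarray, pseudocount: float, background: np.ndarray) -> np.ndarray:
    """Per-column relative-entropy information (bits) of a count matrix
    regularised with `pseudocount`, against `background`.

    Equals 2 - H for a uniform background; used for conserved-window
    refinement where the comparison to background is the point.
    """
    num = counts + pseudocount
    probs = num / num.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs / np.asarray(background, float)[:, None]), 0.0)
    return terms.sum(axis=0)
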