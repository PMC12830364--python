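"""Single-strand PWM scanning with exact null p-values and FDR control.

Every valid window on the given strand is scored by log-odds against an
order-0 background. p-values come from the exact distribution of the
discretised score of a random background window, computed by column-wise
dynamic-programming convolution; q-values are Benjamini-Hochberg, pooled
over every window in the scan batch. Per promoter only the lowest-q hit is
retained, and presence is called at q <= fdr (default 0.1, boundary
inclusive). Windows containing non-ACGT characters are skipped; a promoter
with no valid window is called absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._sequence import encode, require_acgt, window_codes
from .promoters import PromoterRecord
from .pwm import PWM, DEFAULT_PSEUDOCOUNT

log = logging.getLogger(__name__)

DEFAULT_FDR = 0.1
DEFAULT_GRANULARITY = 0.01  # bits


@dataclass(frozen=True)
class ScanHit:
    promoter_id: str
    species_id: str
    offset: int  # 0-based
    matched: str
    score: float  # log-odds, bits
    p: float
    q: float


@dataclass(frozen=True)
class PresenceCall:
    species_id: str
    gene_id: str
    family: str
    status: str  # "present" | "absent"
    best_hit: ScanHit | None

    @property
    def present(self) -> bool:
        return self.status == "present"


def score_logodds(pwm: PWM, window: str) -> float:
    """Log-odds score (bits) of a single w-mer: sum of log2(p/bg)."""
    codes = require_acgt(window, what="window")
    if codes.shape[0] != pwm.width:
        raise ValueError(f"window length {codes.shape[0]} != PWM width {pwm.width}")
    return float(pwm.logodds[codes, np.arange(pwm.width)].sum())


class ScorePValueTable:
    """Exact null distribution of the discretised log-odds score.

    Column scores are rounded to integer multiples of `granularity` (bits);
    the distribution of their sum under i.i.d. background draws is built by
    convolving one column at a time. pvalue(s) = P(score >= s) with s
    discretised the same way, so table lookups agree with full enumeration
    to within one granularity bin.
    """

    def __init__(self, pwm: PWM, background: np.ndarray | None = None,
                 granularity: float = DEFAULT_GRANULARITY):
        if granularity <= 0:
            raise ValueError("granularity must be > 0")
        bg = pwm.background if background is None else np.asarray(background, float)
        self.granularity = float(granularity)
        with np.errstate(divide="ignore"):
            lo = np.log2(pwm.probs / bg[:, None])
        if not np.isfinite(lo).all():
            raise ValueError("PWM has zero probabilities; use a pseudocount before scanning")
        self.int_logodds = np.rint(lo / granularity).astype(np.int64)  # (4, w)
        w = pwm.width

        col_min = self.int_logodds.min(axis=0)
        col_max = self.int_logodds.max(axis=0)
        self.min_score = int(col_min.sum())
        self.max_score = int(col_max.sum())
        size = self.max_score - self.min_score + 1

        dist = np.zeros(size)
        dist[0] = 1.0  # offset relative to running minimum
        cur_lo = 0
        for c in range(w):
            new = np.zeros(size)
            for a in range(4):
                shift = self.int_logodds[a, c] - col_min[c]
                if bg[a] > 0:
                    new[shift : shift + size - shift] += bg[a] * dist[: size - shift]
            dist = new
            cur_lo += col_min[c]
        assert cur_lo == self.min_score
        # survival function: sf[i] = P(score_int >= min_score + i)
        self.sf = np.minimum(1.0, np.cumsum(dist[::-1])[::-1])

    def int_scores(self, win: np.ndarray) -> np.ndarray:
        """Discretised scores for an (m, w) matrix of window codes."""
        w = self.int_logodds.shape[1]
        return self.int_logodds[win, np.arange(w)].sum(axis=1)

    def pvalue_int(self, s: np.ndarray | int) -> np.ndarray | float:
        idx = np.clip(np.asarray(s) - self.min_score, 0, self.sf.shape[0] - 1)
        p = self.sf[idx]
        return np.where(np.asarray(s) > self.max_score, 0.0, p)

    def pvalue(self, score_bits: float) -> float:
        s = int(np.rint(score_bits / self.granularity))
        if s <= self.min_score:
            return 1.0
        return float(self.pvalue_int(s))


def exact_pvalue_table(
    pwm: PWM, background: np.ndarray | None = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> ScorePValueTable:
    """Build the exact score -> p-value mapping for a PWM (see
    ScorePValueTable)."""
    return ScorePValueTable(pwm, background=background, granularity=granularity)


def bh_qvalues(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan(
    pwm: PWM,
    promoters: Sequence[PromoterRecord],
    fdr: float = DEFAULT_FDR,
    *,
    pooling: str = "batch",
    granularity: float = DEFAULT_GRANULARITY,
    table: ScorePValueTable | None = None,
) -> tuple[list[ScanHit], list[PresenceCall]]:
    """Scan the given strand of each promoter; per promoter only the
    lowest-q hit is kept (ties: leftmost) and presence is called iff its
    q <= fdr (boundary inclusive).

    pooling controls the multiple-testing batch for the Benjamini-Hochberg
    step-up. "batch" (default, the genome-scanning convention) pools every
    window of the whole scan; "per_promoter" adjusts each promoter's
    windows separately, which grants every promoter its own alpha-level
    family and is markedly more liberal — use it only to probe pooling
    sensitivity. The choice is logged. Note that at fdr 0.1 a batch
    containing k genuine sites admits ~0.1*k false presences in
    expectation; absence claims should be read with that in mind.
    """
    if not promoters:
        raise ValueError("promoters must be non-empty")
    if pooling not in ("per_promoter", "batch"):
        raise ValueError(f"unknown pooling {pooling!r}")
    log.info("scan: %d promoters, w=%d, fdr=%g, q-value pooling=%s",
             len(promoters), pwm.width, fdr, pooling)
    table = table or exact_pvalue_table(pwm, granularity=granularity)
    w = pwm.width

    per_prom: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    all_p: list[np.ndarray] = []
    for rec in promoters:
        win, valid = window_codes(encode(rec.sequence), w)
        offs = np.flatnonzero(valid)
        if offs.size:
            iscores = table.int_scores(win[offs])
            p = np.asarray(table.pvalue_int(iscores), dtype=float)
        else:
            iscores = np.empty(0, dtype=np.int64)
            p = np.empty(0)
        per_prom.append((offs, iscores, p))
        all_p.append(p)

    if pooling == "batch":
        pooled = np.concatenate(all_p) if all_p else np.empty(0)
        q = bh_qvalues(pooled) if pooled.size else pooled
    else:
        q = np.concatenate(
            [bh_qvalues(p) if p.size else p for p in all_p]
        ) if all_p else np.empty(0)

    hits: list[ScanHit] = []
    calls: list[PresenceCall] = []
    cursor = 0
    for rec, (offs, iscores, p) in zip(promoters, per_prom):
        m = offs.size
        qs = q[cursor : cursor + m]
        cursor += m
        if m == 0:
            calls.append(PresenceCall(rec.species_id, rec.gene_id, rec.family, "absent", None))
            continue
        j = int(np.argmin(qs))  # lowest q; argmin is leftmost on ties
        offset = int(offs[j])
        hit = ScanHit(
            promoter_id=rec.gene_id,
            species_id=rec.species_id,
            offset=offset,
            matched=rec.sequence[offset : offset + w].upper(),
            score=float(iscores[j] * table.granularity),
            p=float(p[j]),
            q=float(qs[j]),
        )
        hits.append(hit)
        status = "present" if hit.q <= fdr else "absent"
        calls.append(
            PresenceCall(rec.species_id, rec.gene_id, rec.family, status,
                         hit if status == "present" else hit)
        )
    return hits, calls


def best_hit_per_species(calls: Iterable[PresenceCall]) -> dict[str, str]:
    """One gene per species: the present call with the lowest best-hit p
    (ties: lowest q, then leftmost offset, then lexicographic gene_id).
    Species with no present call are omitted and logged."""
    best: dict[str, PresenceCall] = {}
    seen: set[str] = set()
    for call in calls:
        seen.add(call.species_id)
        if not call.present or call.best_hit is None:
            continue
        key = (call.best_hit.p, call.best_hit.q, call.best_hit.offset, call.gene_id)
        prev = best.get(call.species_id)
        if prev is None or key < (prev.best_hit.p, prev.best_hit.q,
                                  prev.best_hit.offset, prev.gene_id):
            best[call.species_id] = call
    for sp in sorted(seen - best.keys()):
        log.warning("best_hit_per_species: species %s has no present call; omitted", sp)
    return {sp: call.gene_id for sp, call in sorted(best.items())}


def consensus_pwm(
    hits: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    *,
    background: np.ndarray | None = None,
) -> PWM:
    """Consensus matrix from one matched w-mer per species: column
    frequencies plus pseudocount, normalised."""
    if not hits:
        raise ValueError("need at least one matched w-mer")
    if len({len(h) for h in hits}) != 1:
        raise ValueError("matched w-mers must all have equal length")
    return PWM.from_sites(list(hits), pseudocount=pseudocount, background=background)
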