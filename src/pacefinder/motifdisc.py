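"""Fixed-width ZOOPS motif discovery, discriminative and normal mode.

The model is the classic "zero or one occurrence per sequence" mixture: a
sequence either contains one motif site at an unknown offset (probability
gamma, offset uniform over valid windows) or is pure background. EM
alternates a posterior over site offsets (plus the no-site event) with
re-estimation of the PWM and gamma; the reported objective is the
ZOOPS log-likelihood ratio against the all-background model plus the
pseudocount's Dirichlet prior term, in bits (the MAP objective EM never
decreases).

Discovery seeds EM from w-mers of the positive set. Every seed receives a
cheap vectorised one-step objective; only the top few are refined by full
EM (the standard MEME-style economy). Uniformly subsampled seeds are
supplemented with "anchor" seeds built around exact 8-mers shared by the
most positive sequences, so that a degraded implant present once per
sequence is reliably seeded even when the w-mer universe is large.

Only the given strand is ever searched; windows containing non-ACGT
characters are skipped everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom, poisson

from ._sequence import decode, encode, window_codes
from .promoters import DiscoverySets, PromoterRecord, build_sets
from .pwm import PWM, DEFAULT_PSEUDOCOUNT, column_information

log = logging.getLogger(__name__)

LOG2 = np.log2


class MissingControlError(ValueError):
    """Discriminative discovery requires a non-empty control set."""


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------


class _SeqWindows:
    """Flattened valid windows of a sequence set at one width."""

    def __init__(self, seqs: Sequence[str], w: int):
        self.w = w
        self.n_seq = len(seqs)
        wins, offs, counts = [], [], []
        for s in seqs:
            win, valid = window_codes(encode(s), w)
            idx = np.flatnonzero(valid)
            wins.append(win[idx])
            offs.append(idx)
            counts.append(idx.size)
        self.m = np.asarray(counts, dtype=np.int64)  # valid windows per seq
        self.win = (
            np.concatenate(wins) if wins else np.empty((0, w), dtype=np.int8)
        )
        self.offsets = np.concatenate(offs) if offs else np.empty(0, dtype=np.int64)
        self.ptr = np.concatenate([[0], np.cumsum(self.m)])
        self.seq_index = np.repeat(np.arange(self.n_seq), self.m)
        self.nonempty = np.flatnonzero(self.m > 0)
        self._onehot: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.win.shape[0]

    @property
    def onehot(self) -> np.ndarray:
        """(N, 4w) float32 one-hot encoding, layout [pos0 ACGT, pos1 ACGT, ...]."""
        if self._onehot is None:
            n, w = self.win.shape
            x = np.zeros((n, 4 * w), dtype=np.float32)
            if n:
                x[np.arange(n)[:, None], np.arange(w) * 4 + self.win] = 1.0
            self._onehot = x
        return self._onehot

    def reduce_lse2(self, t: np.ndarray) -> np.ndarray:
        """Per-sequence log2-sum-exp2 over windows; shape (n_nonempty,) or
        (n_nonempty, c) for 2-D input."""
        starts = self.ptr[:-1][self.nonempty]
        mx = np.maximum.reduceat(t, starts, axis=0)
        shifted = np.exp2(t - np.repeat(mx, self.m[self.nonempty], axis=0))
        return mx + LOG2(np.add.reduceat(shifted, starts, axis=0))


def _best_site_scores(seqs: Sequence[str], logodds: np.ndarray) -> np.ndarray:
    """Best valid-window log-odds per sequence (-inf when none)."""
    w = logodds.shape[1]
    cols = np.arange(w)
    out = np.full(len(seqs), -np.inf)
    for i, s in enumerate(seqs):
        win, valid = window_codes(encode(s), w)
        if valid.any():
            out[i] = logodds[win[valid], cols].sum(axis=1).max()
    return out


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Occurrence:
    seq_index: int
    offset: int
    matched: str
    score: float  # best-site log-odds, bits
    site_posterior: float  # posterior that the sequence has a site
    window_posterior: float  # posterior of this particular offset


@dataclass
class MotifModel:
    pwm: PWM
    gamma: float
    objective: float  # ZOOPS log-likelihood ratio vs background, bits
    significance: float  # mode-dependent; see discover()
    occurrences: list[Occurrence]
    trace: list[float] = field(default_factory=list)
    mode: str = "normal"
    width_searched: int | None = None
    threshold: float | None = None  # score threshold at minimal significance

    @property
    def width(self) -> int:
        return self.pwm.width

    @property
    def consensus(self) -> str:
        return self.pwm.consensus

    def sites(self, min_site_posterior: float = 0.5) -> list[Occurrence]:
        return [o for o in self.occurrences if o.site_posterior >= min_site_posterior]


@dataclass
class PassRecord:
    name: str
    design: str
    mode: str
    widths: tuple[int, ...]
    model: MotifModel
    details: dict = field(default_factory=dict)


@dataclass
class ProtocolReport:
    passes: list[PassRecord]
    final_pwm: PWM
    one_per_species: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.passes) != 4:
            raise ValueError("the focal protocol has exactly four passes")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscoveryConfig:
    max_seeds: int = 2000
    n_refine: int = 3  # seeds refined by full EM per width
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    gamma0: float = 0.5
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0
    report_threshold: float = 0.05  # stop multi-motif rounds past this
    anchor_k: int = 8  # exact word length for anchor seeds
    anchor_top: int = 20  # how many top shared words to expand
    seed_chunk: int = 256  # seeds scored per matmul chunk


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def seed_candidates(
    positives: Sequence[str], w: int, max_seeds: int, seed: int = 0
) -> list[PWM]:
    """One soft-consensus PWM (0.7 on the seed base, 0.1 elsewhere) per
    distinct valid w-mer of the positive set, subsampled uniformly to
    max_seeds with the pipeline seed when there are more."""
    if w < 4:
        raise ValueError("width must be >= 4")
    sw = _SeqWindows(list(positives), w)
    if sw.n_windows == 0:
        raise ValueError(f"no sequence of length >= {w} in the positive set")
    codes = _distinct_windows(sw.win)
    codes = _subsample_rows(codes, max_seeds, np.random.default_rng(seed))
    return [PWM.from_consensus(decode(row)) for row in codes]


def _distinct_windows(win: np.ndarray) -> np.ndarray:
    """Distinct rows of an (N, w) code matrix, in order of first appearance."""
    seen: dict[bytes, None] = {}
    for row in win:
        seen.setdefault(row.tobytes())
    w = win.shape[1]
    return np.frombuffer(b"".join(seen), dtype=np.int8).reshape(-1, w).copy()


def _subsample_rows(codes: np.ndarray, max_rows: int, rng: np.random.Generator) -> np.ndarray:
    if codes.shape[0] <= max_rows:
        return codes
    idx = np.sort(rng.choice(codes.shape[0], size=max_rows, replace=False))
    return codes[idx]


def _anchor_windows(sw: _SeqWindows, k: int, top: int) -> np.ndarray:
    """Seed windows anchored on exact k-mers shared by the most sequences.

    For each of the `top` k-mers present in the largest number of distinct
    sequences (at least 2), one occurrence is located and every w-window
    placement covering it is emitted, so at least one seed aligns with a
    shared degraded element regardless of its registration."""
    w = sw.w
    k = min(k, w)
    if sw.n_windows == 0:
        return np.empty((0, w), dtype=np.int8)
    # integer-encode the k-mer starting at each valid window start
    kk = sw.win[:, :k].astype(np.int64)
    key = kk @ (4 ** np.arange(k - 1, -1, -1))
    # count distinct sequences per k-mer
    order = np.lexsort((sw.seq_index, key))
    ks, si = key[order], sw.seq_index[order]
    first = np.ones(ks.shape[0], dtype=bool)
    first[1:] = (ks[1:] != ks[:-1]) | (si[1:] != si[:-1])
    uk, counts = np.unique(ks[first], return_counts=True)
    good = counts >= 2
    if not good.any():
        return np.empty((0, w), dtype=np.int8)
    top_kmers = uk[good][np.argsort(counts[good])[::-1][:top]]
    rows = []
    for km in top_kmers:
        j = int(np.flatnonzero(key == km)[0])  # first occurrence window
        # all placements of the k-mer inside a w-window are other windows of
        # the same sequence shifted left by 0..w-k
        seq = sw.seq_index[j]
        off = sw.offsets[j]
        lo, hi = sw.ptr[seq], sw.ptr[seq + 1]
        block = sw.offsets[lo:hi]
        for shift in range(w - k + 1):
            pos = np.searchsorted(block, off - shift)
            if pos < block.size and block[pos] == off - shift:
                rows.append(sw.win[lo + pos])
    if not rows:
        return np.empty((0, w), dtype=np.int8)
    return _distinct_windows(np.asarray(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def em_zoops(
    init: PWM,
    positives: Sequence[str],
    background: np.ndarray | None = None,
    gamma0: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    _windows: _SeqWindows | None = None,
) -> MotifModel:
    """Fit the ZOOPS mixture by EM from an initial PWM.

    Returns the converged model with the MAP ZOOPS log-likelihood ratio
    against the all-background model (bits; includes the Dirichlet prior
    term induced by the pseudocount, which is what EM provably never
    decreases) as objective, plus the full per-iteration trace. gamma0 == 0 is the
    degenerate no-responsibility case: the initial PWM is returned unchanged.
    """
    if not positives and _windows is None:
        raise ValueError("positive set is empty")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    bg = np.asarray(background, float) if background is not None else init.background
    w = init.width
    seqs = list(positives)
    if any(len(s) < w for s in seqs):
        raise ValueError(f"all sequences must have length >= motif width {w}")

    if gamma0 == 0.0:
        return MotifModel(
            pwm=init, gamma=0.0, objective=0.0, significance=float("nan"),
            occurrences=[], trace=[0.0],
        )

    sw = _windows if _windows is not None else _SeqWindows(seqs, w)
    if sw.n_windows == 0:
        raise ValueError("no valid (ACGT-only) windows in the positive set")
    X = sw.onehot
    log2m = LOG2(np.maximum(sw.m, 1).astype(float))

    probs = init.probs.copy()
    gamma = float(np.clip(gamma0, 1e-9, 1 - 1e-9))
    trace: list[float] = []
    z = np.zeros(sw.n_windows)
    prev = -np.inf

    def _prior_term(p: np.ndarray) -> float:
        # Dirichlet prior matching the pseudocount M-step, anchored at the
        # background so the objective stays a "bits vs background" quantity;
        # without it the pseudocount M-step would not guarantee EM ascent.
        if pseudocount <= 0:
            return 0.0
        return float(pseudocount * LOG2(p / bg[:, None]).sum())

    cols = np.arange(w)
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            lo = LOG2(probs / bg[:, None])
        # float64 exact scoring: float32 matmul noise (~1e-5 bits) would
        # break the ascent guarantee near convergence
        s = lo[sw.win, cols].sum(axis=1)
        t = s + LOG2(gamma) - log2m[sw.seq_index]
        lse = sw.reduce_lse2(t)  # per nonempty sequence
        zlog = np.logaddexp2(LOG2(1.0 - gamma), lse)  # log2 Z_i
        ll = float(zlog.sum()) + _prior_term(probs)
        trace.append(ll)

        z = np.exp2(t - np.repeat(zlog, sw.m[sw.nonempty]))
        counts = (z.astype(np.float32) @ X).astype(np.float64).reshape(w, 4).T
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=0)
        site_mass = float(z.sum())
        gamma = float(np.clip(site_mass / sw.n_seq, 1e-9, 1 - 1e-9))

        if prev > -np.inf and abs(ll - prev) <= tol * max(1.0, abs(ll)):
            break
        prev = ll

    pwm = PWM(probs, background=bg, pseudocount=pseudocount)
    with np.errstate(divide="ignore"):
        lo = LOG2(probs / bg[:, None])
    s = lo[sw.win, cols].sum(axis=1)

    occurrences: list[Occurrence] = []
    for pos, i in enumerate(sw.nonempty):
        a, b = sw.ptr[i], sw.ptr[i + 1]
        zi = z[a:b]
        j = int(np.argmax(zi))
        occurrences.append(
            Occurrence(
                seq_index=int(i),
                offset=int(sw.offsets[a + j]),
                matched=decode(sw.win[a + j]),
                score=float(s[a + j]),
                site_posterior=float(zi.sum()),
                window_posterior=float(zi[j]),
            )
        )
    return MotifModel(
        pwm=pwm, gamma=gamma, objective=trace[-1], significance=float("nan"),
        occurrences=occurrences, trace=trace,
    )


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def _fisher_significance(
    pos_best: np.ndarray, ctrl_best: np.ndarray
) -> tuple[float, float]:
    """One-sided Fisher exact p on presence (best-site score >= threshold),
    minimised over thresholds taken from the positive best scores."""
    n_pos, n_ctrl = pos_best.size, ctrl_best.size
    best_p, best_t = 1.0, float("inf")
    for t in np.unique(pos_best)[::-1]:
        a = int((pos_best >= t).sum())
        b = int((ctrl_best >= t).sum())
        p = float(hypergeom.sf(a - 1, n_pos + n_ctrl, a + b, n_pos))
        if p < best_p:
            best_p, best_t = p, float(t)
    return best_p, best_t


def _poisson_significance(
    model: MotifModel, pos_best: np.ndarray, m: np.ndarray
) -> tuple[float, float]:
    """Normal-mode E-value analogue: Poisson upper tail on the number of
    sequences whose best site beats a threshold, against the exact null."""
    from .motifscan import exact_pvalue_table

    table = exact_pvalue_table(model.pwm)
    best_p, best_t = 1.0, float("inf")
    for t in np.unique(pos_best)[::-1]:
        p_win = table.pvalue(float(t))
        lam = float((1.0 - (1.0 - min(p_win, 1.0)) ** m).sum())
        k = int((pos_best >= t).sum())
        p = float(poisson.sf(k - 1, lam)) if lam > 0 else (0.0 if k > 0 else 1.0)
        if p < best_p:
            best_p, best_t = p, float(t)
    return best_p, best_t


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------


def _order0_background(seqs: Sequence[str]) -> np.ndarray:
    counts = np.ones(4)  # one pseudo-observation per base
    for s in seqs:
        codes = encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    return counts / counts.sum()


def _prescore_seeds(
    sw: _SeqWindows, seeds: np.ndarray, bg: np.ndarray, gamma0: float, chunk: int
) -> np.ndarray:
    """Approximate one-step ZOOPS objective for every seed (rows of w-mer
    codes): the per-sequence site sum is replaced by its best window, which
    is tight for the peaked seed models and only used to rank seeds."""
    n_seeds, w = seeds.shape
    match = LOG2(0.7 / bg)  # per-base log-odds when the seed base matches
    miss = LOG2(0.1 / bg)
    # (S, 4w) seed log-odds in onehot layout
    seedlo = np.tile(miss.astype(np.float32), (n_seeds, w))
    cols = np.arange(w) * 4 + seeds
    rows = np.arange(n_seeds)[:, None]
    seedlo[rows, cols] = match[seeds].astype(np.float32)

    X = sw.onehot
    log2m = LOG2(np.maximum(sw.m, 1).astype(float))
    prior = (LOG2(gamma0) - log2m[sw.nonempty]).astype(np.float32)
    lognogamma = LOG2(1.0 - gamma0)
    starts = sw.ptr[:-1][sw.nonempty]
    m_nonempty = sw.m[sw.nonempty]
    uniform = bool((m_nonempty == m_nonempty[0]).all()) if m_nonempty.size else True
    obj = np.empty(n_seeds)
    for start in range(0, n_seeds, chunk):
        sl = slice(start, min(start + chunk, n_seeds))
        scores = X @ seedlo[sl].T
        if uniform and m_nonempty.size:
            mx = scores.reshape(m_nonempty.size, m_nonempty[0], -1).max(axis=1)
        else:
            mx = np.maximum.reduceat(scores, starts, axis=0)
        mx = mx + prior[:, None]
        obj[sl] = np.logaddexp2(lognogamma, mx.astype(np.float64)).sum(axis=0)
    return obj


def discover(
    sets: DiscoverySets,
    widths: int | Iterable[int],
    mode: str = "discriminative",
    n_motifs: int = 1,
    cfg: DiscoveryConfig | None = None,
) -> list[MotifModel]:
    """Discover up to n_motifs fixed-width motifs on the given strand.

    Per width: seed from distinct w-mers (uniform subsample to max_seeds,
    plus shared-word anchor seeds), prescore every seed with a one-step
    ZOOPS objective, refine the best few by full EM, keep the model with the
    best mode objective. Across widths the winner is the model with the
    smallest significance (discriminative: one-sided Fisher exact on the
    presence split vs controls; normal: Poisson tail on sequences beating
    the exact-null threshold). Additional motifs are found after masking the
    previous motif's sites with N.
    """
    cfg = cfg or DiscoveryConfig()
    if mode not in ("discriminative", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "discriminative" and not sets.controls:
        raise MissingControlError("discriminative mode requires a non-empty control set")
    if not sets.positives:
        raise ValueError("positive set is empty")
    width_list = [int(widths)] if isinstance(widths, int) else [int(x) for x in widths]

    pos_seqs = [p.sequence.upper() for p in sets.positives]
    ctrl_seqs = [c.sequence.upper() for c in sets.controls]
    bg = _order0_background(ctrl_seqs if mode == "discriminative" else pos_seqs)
    log.info("discover: mode=%s, background estimated from %s (%s)",
             mode, "controls" if mode == "discriminative" else "positives",
             np.array2string(bg, precision=3))
    rng = np.random.default_rng(cfg.seed)
    n_pos, n_ctrl = len(pos_seqs), len(ctrl_seqs)

    working = list(pos_seqs)
    results: list[MotifModel] = []

    for round_idx in range(n_motifs):
        best: MotifModel | None = None
        for w in width_list:
            usable_idx = [i for i, s in enumerate(working) if len(s) >= w]
            if not usable_idx:
                continue
            usable = [working[i] for i in usable_idx]
            sw = _SeqWindows(usable, w)
            if sw.n_windows == 0:
                continue
            seeds = _distinct_windows(sw.win)
            seeds = _subsample_rows(seeds, cfg.max_seeds, rng)
            anchors = _anchor_windows(sw, cfg.anchor_k, cfg.anchor_top)
            if anchors.size:
                seeds = _distinct_windows(np.concatenate([seeds, anchors]))

            obj = _prescore_seeds(sw, seeds, bg, cfg.gamma0, cfg.seed_chunk)
            top = np.argsort(obj)[::-1][: cfg.n_refine]

            width_best: MotifModel | None = None
            for si in top:
                model = em_zoops(
                    PWM.from_consensus(decode(seeds[si]), background=bg),
                    usable,
                    background=bg,
                    gamma0=cfg.gamma0,
                    tol=cfg.tol,
                    max_iter=cfg.max_iter,
                    pseudocount=cfg.pseudocount,
                    _windows=sw,
                )
                model.mode = mode
                model.width_searched = w
                pos_best = _best_site_scores(usable, model.pwm.logodds)
                if mode == "discriminative":
                    ctrl_best = _best_site_scores(ctrl_seqs, model.pwm.logodds)
                    penalty = n_pos * float(np.maximum(ctrl_best, 0.0).mean())
                    model.objective = model.objective - penalty
                    sig, thr = _fisher_significance(pos_best, ctrl_best)
                else:
                    sig, thr = _poisson_significance(model, pos_best, sw.m)
                model.significance = sig
                model.threshold = thr
                # remap occurrence seq indices to the unmasked positive list
                model.occurrences = [
                    replace(o, seq_index=usable_idx[o.seq_index])
                    for o in model.occurrences
                ]
                if width_best is None or model.objective > width_best.objective:
                    width_best = model
            if width_best is None:
                continue
            if (
                best is None
                or width_best.significance < best.significance
                or (
                    width_best.significance == best.significance
                    and width_best.objective > best.objective
                )
            ):
                best = width_best
        if best is None:
            break
        if round_idx > 0 and best.significance > cfg.report_threshold:
            log.info("discover: stopping after %d motifs (significance %.3g)",
                     round_idx, best.significance)
            break
        results.append(best)
        if round_idx + 1 < n_motifs:
            working = _mask_sites(working, best)
    return results


def _mask_sites(seqs: list[str], model: MotifModel) -> list[str]:
    out = list(seqs)
    w = model.width
    for occ in model.sites():
        s = out[occ.seq_index]
        out[occ.seq_index] = s[: occ.offset] + "N" * w + s[occ.offset + w :]
    return out


# ---------------------------------------------------------------------------
# width refinement
# ---------------------------------------------------------------------------


def refine_window(
    occurrences: Sequence[str] | np.ndarray,
    target_w: int,
    ic_threshold: float = 1.0,
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> int:
    """Offset of the length-target_w window with the largest summed
    per-column information content in an aligned site matrix (rows over
    {A,C,G,T,N}; N is treated as missing). Ties go to the leftmost window.

    ic_threshold is informational: the count of columns at or above it is
    logged so the conserved core is visible in run logs.
    """
    if isinstance(occurrences, np.ndarray):
        rows = occurrences
    else:
        rows = np.stack([encode(s) for s in occurrences])
    n, aln_w = rows.shape
    if target_w > aln_w:
        raise ValueError(f"target width {target_w} exceeds alignment width {aln_w}")
    bg = np.asarray(background, float) if background is not None else np.full(4, 0.25)
    counts = np.zeros((4, aln_w))
    for a in range(4):
        counts[a] = (rows == a).sum(axis=0)
    ic = column_information(counts, pseudocount, bg)
    log.info("refine_window: %d/%d columns with IC >= %.2f bits",
             int((ic >= ic_threshold).sum()), aln_w, ic_threshold)
    sums = np.convolve(ic, np.ones(target_w), mode="valid")
    return int(np.argmax(sums))  # argmax returns the leftmost maximiser


# ---------------------------------------------------------------------------
# the four-pass protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolConfig:
    core_width: int = 29
    wide_width: int = 45
    width_grid: tuple[int, ...] = tuple(range(6, 51))
    fdr: float = 0.1
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)


def run_pace_protocol(
    promoters: Sequence[PromoterRecord],
    species,
    tree=None,
    cfg: ProtocolConfig | None = None,
) -> ProtocolReport:
    """Four sequential discovery passes mirroring the clade-restricted
    element search:

    A. discriminative discovery over the width grid, nodulating-clade focal
       promoters vs (non-clade focal + all paralogue) controls;
    B. normal-mode discovery on the positives at the wide width, then
       conserved-window refinement down to the core width;
    C. discriminative discovery at the fixed core width, followed by a scan
       that keeps the single best-scoring focal promoter per species
       (lowest site p-value);
    D. discriminative discovery at the core width on that one-per-species
       positive set, removing per-species sequence bias. Pass D's PWM is
       the final consensus.
    """
    from .motifscan import best_hit_per_species, scan

    cfg = cfg or ProtocolConfig()
    dcfg = cfg.discovery
    passes: list[PassRecord] = []

    # Pass A ---------------------------------------------------------------
    sets_disc = build_sets(promoters, species, "discriminative")
    model_a = discover(sets_disc, cfg.width_grid, "discriminative", 1, dcfg)[0]
    passes.append(PassRecord("A", "discriminative", "discriminative",
                             tuple(cfg.width_grid), model_a))

    # Pass B ---------------------------------------------------------------
    sets_norm = build_sets(promoters, species, "normal")
    model_b = discover(sets_norm, cfg.wide_width, "normal", 1, dcfg)[0]
    aligned = [o.matched for o in model_b.sites()] or [o.matched for o in model_b.occurrences]
    offset = refine_window(
        aligned, cfg.core_width,
        pseudocount=dcfg.pseudocount, background=model_b.pwm.background,
    )
    passes.append(PassRecord(
        "B", "normal", "normal", (cfg.wide_width,), model_b,
        details={"refined_offset": offset,
                 "refined_consensus": model_b.consensus[offset : offset + cfg.core_width]},
    ))

    # Pass C ---------------------------------------------------------------
    model_c = discover(sets_disc, cfg.core_width, "discriminative", 1, dcfg)[0]
    _, calls = scan(model_c.pwm, sets_disc.positives, fdr=cfg.fdr)
    best_map = best_hit_per_species(calls)
    passes.append(PassRecord("C", "discriminative", "discriminative",
                             (cfg.core_width,), model_c,
                             details={"best_per_species": dict(best_map)}))

    # Pass D ---------------------------------------------------------------
    sets_d = build_sets(promoters, species, "one_per_species",
                        best_per_species=best_map)
    model_d = discover(sets_d, cfg.core_width, "discriminative", 1, dcfg)[0]
    passes.append(PassRecord("D", "one_per_species", "discriminative",
                             (cfg.core_width,), model_d))

    report = ProtocolReport(passes=passes, final_pwm=model_d.pwm,
                            one_per_species=dict(best_map))
    if report.final_pwm.width != cfg.core_width:
        raise AssertionError("final PWM width must equal the configured core width")
    return report
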