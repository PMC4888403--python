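"""Copy-number calling with an 11-state negative-binomial hidden Markov model.

Hidden states are integer copy numbers 0..10 (nullisomy to decasomy).
The nullisomy emission is a point mass at zero; every other state s emits
negative-binomially with mean and variance tied to s times the monosomy
(haploid-unit) mean mu1 and variance var1.  Writing p = mu1 / var1 and
r_s = s * mu1^2 / (var1 - mu1), the success probability is shared across
states and the size parameter scales linearly in s — only two emission
parameters are free, which is what keeps the model identifiable from a
single shallow library.

Parameters are estimated by Baum-Welch (EM); the per-bin call is the
state with the highest posterior marginal probability (Viterbi decoding
is available as an option).

Usage follows the model/results convention::

    model = CopyNumberHMM(cell.observable(), grid)
    res = model.fit()
    res.states          # per-bin integer copy number
    res.segments()      # maximal constant-state runs per chromosome
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .bins import BinGrid

__all__ = [
    "EmissionModel",
    "CopyNumberHMM",
    "CopyNumberHMMResults",
    "fit_copy_number_hmm",
    "decode_segments",
]

_LOG_ZERO = -1e300


@dataclass(frozen=True)
class EmissionModel:
    """Tied-moment emission family over copy-number states 0..s_max.

    State 0 is a delta at zero; state s >= 1 is NB with mean s*mu1 and
    variance s*var1, which requires var1 > mu1 (overdispersion).
    """

    mu1: float
    var1: float
    s_max: int = 10

    def __post_init__(self) -> None:
        if self.mu1 <= 0:
            raise ValueError("mu1 must be positive")
        if self.var1 <= self.mu1:
            raise ValueError("var1 must exceed mu1 (negative binomial)")
        if self.s_max < 1:
            raise ValueError("s_max must be >= 1")

    @property
    def nb_p(self) -> float:
        """Shared NB success probability mu1/var1 (state-independent)."""
        return self.mu1 / self.var1

    def nb_r(self, s: int | np.ndarray) -> float | np.ndarray:
        """NB size parameter for state s: s * mu1^2 / (var1 - mu1)."""
        return s * self.mu1**2 / (self.var1 - self.mu1)

    def state_mean(self, s: int) -> float:
        return s * self.mu1

    def state_var(self, s: int) -> float:
        return s * self.var1

    def log_pmf_matrix(self, x: np.ndarray) -> np.ndarray:
        """Log emission probabilities, shape (n_bins, s_max + 1).

        Column 0 is the nullisomy delta: 0 for x == 0, effectively -inf
        otherwise.  Columns s >= 1 are NB(r_s, p) log-pmfs.
        """
        x = np.asarray(x, dtype=np.int64)
        n = len(x)
        out = np.full((n, self.s_max + 1), _LOG_ZERO)
        out[:, 0] = np.where(x == 0, 0.0, _LOG_ZERO)
        p = self.nb_p
        states = np.arange(1, self.s_max + 1)
        r = self.nb_r(states)[None, :]  # (1, S)
        xc = x[:, None].astype(float)
        out[:, 1:] = (
            gammaln(xc + r)
            - gammaln(r)
            - gammaln(xc + 1.0)
            + r * np.log(p)
            + xc * np.log1p(-p)
        )
        return out


# decoding tie-break: prefer the state nearest copy number 2, then the smaller
def _state_priority(s_max: int) -> np.ndarray:
    return np.array(sorted(range(s_max + 1), key=lambda s: (abs(s - 2), s)))


class CopyNumberHMM:
    """HMM copy-number model for one cell's (GC-corrected) bin counts.

    Parameters
    ----------
    counts
        Per-bin observable values; rounded to the nearest non-negative
        integer for negative-binomial evaluation.
    grid
        Optional :class:`BinGrid` aligned with ``counts``; needed for
        segment decoding and chromosome-aware outputs.
    s_max
        Largest modelled copy number (default 10, i.e. decasomy).
    """

    def __init__(
        self,
        counts: Sequence[float] | np.ndarray,
        grid: BinGrid | None = None,
        s_max: int = 10,
    ) -> None:
        x = np.asarray(counts, dtype=float)
        if np.any(x < 0):
            raise ValueError("counts must be non-negative")
        if len(x) < 50:
            raise ValueError("need at least 50 bins to fit the copy-number HMM")
        if grid is not None and grid.n_bins != len(x):
            raise ValueError("grid does not match count vector length")
        self.endog = np.rint(x).astype(np.int64)
        self.grid = grid
        self.s_max = int(s_max)

    # -- initialisation --------------------------------------------------
    def _init_params(self) -> tuple[EmissionModel, np.ndarray, np.ndarray]:
        x = self.endog
        nz = x[x > 0]
        mu1 = max(float(nz.mean()) / 2.0, 1e-3)
        var1 = max(float(nz.var()) / 2.0, 1.2 * mu1)
        S = self.s_max + 1
        transition = np.full((S, S), 0.01 / (S - 1))
        np.fill_diagonal(transition, 0.99)
        initial = np.full(S, 0.02 / max(S - 4, 1))
        for s in range(1, min(5, S)):
            initial[s] = 0.98 / 4
        initial /= initial.sum()
        return EmissionModel(mu1, var1, self.s_max), transition, initial

    # -- inference primitives -------------------------------------------
    @staticmethod
    def _forward_backward(
        log_b: np.ndarray, transition: np.ndarray, initial: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Scaled forward-backward.

        Returns (gamma, xi_sum, log_likelihood) where gamma is the
        (n, S) posterior state marginal and xi_sum the (S, S) expected
        transition-count matrix.
        """
        n, S = log_b.shape
        # per-row shift keeps linear-space emissions in range
        shift = log_b.max(axis=1)
        b = np.exp(log_b - shift[:, None])

        alpha = np.empty((n, S))
        c = np.empty(n)  # scaling factors
        a = initial * b[0]
        c[0] = a.sum()
        alpha[0] = a / c[0]
        for t in range(1, n):
            a = (alpha[t - 1] @ transition) * b[t]
            c[t] = a.sum()
            alpha[t] = a / c[t]

        beta = np.empty((n, S))
        beta[-1] = 1.0
        for t in range(n - 2, -1, -1):
            beta[t] = (transition @ (b[t + 1] * beta[t + 1])) / c[t + 1]

        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)

        xi_sum = np.zeros((S, S))
        for t in range(n - 1):
            xi = transition * np.outer(alpha[t], b[t + 1] * beta[t + 1]) / c[t + 1]
            xi_sum += xi

        log_likelihood = float(np.log(c).sum() + shift.sum())
        return gamma, xi_sum, log_likelihood

    def _viterbi(
        self, log_b: np.ndarray, transition: np.ndarray, initial: np.ndarray
    ) -> np.ndarray:
        n, S = log_b.shape
        with np.errstate(divide="ignore"):
            log_t = np.log(np.maximum(transition, 1e-300))
            log_i = np.log(np.maximum(initial, 1e-300))
        delta = log_i + log_b[0]
        psi = np.zeros((n, S), dtype=np.int64)
        for t in range(1, n):
            scores = delta[:, None] + log_t
            psi[t] = np.argmax(scores, axis=0)
            delta = scores[psi[t], np.arange(S)] + log_b[t]
        path = np.empty(n, dtype=np.int64)
        path[-1] = int(np.argmax(delta))
        for t in range(n - 2, -1, -1):
            path[t] = psi[t + 1, path[t + 1]]
        return path

    # -- estimation ------------------------------------------------------
    def fit(
        self,
        max_iter: int = 200,
        tol: float = 1e-4,
        decode: str = "posterior",
    ) -> "CopyNumberHMMResults":
        """Estimate parameters by Baum-Welch and decode per-bin states.

        Iterates EM until the relative log-likelihood change drops below
        ``tol`` or ``max_iter`` is reached; the emission M-step is
        posterior-weighted moment matching on the scaled observations
        x_i / s, after which var1 > 1.05 * mu1 is re-imposed so the
        negative binomial stays proper.
        """
        x = self.endog
        if x.sum() == 0:
            # degenerate all-zero library: everything nullisomic
            S = self.s_max + 1
            n = len(x)
            posteriors = np.zeros((n, S))
            posteriors[:, 0] = 1.0
            return CopyNumberHMMResults(
                model=self,
                emission=None,
                transition=np.eye(S),
                initial=np.eye(S)[0],
                log_likelihood=0.0,
                llf_history=[0.0],
                posteriors=posteriors,
                states=np.zeros(n, dtype=np.int64),
                converged=True,
                n_iter=0,
                flags=["all_zero"],
            )

        emission, transition, initial = self._init_params()
        pos_states = np.arange(1, self.s_max + 1)

        def m_step(gamma: np.ndarray, xi_sum: np.ndarray):
            new_initial = gamma[0] / gamma[0].sum()
            row = xi_sum.sum(axis=1, keepdims=True)
            new_transition = np.where(
                row > 0, xi_sum / np.maximum(row, 1e-300), transition
            )
            new_transition /= new_transition.sum(axis=1, keepdims=True)
            # tied emission moments from scaled residuals
            w = gamma[:, 1:]
            wsum = w.sum()
            if wsum > 0:
                scaled = x[:, None] / pos_states[None, :]
                mu1 = max(float(np.sum(w * scaled) / wsum), 1e-3)
                resid2 = (x[:, None] - pos_states[None, :] * mu1) ** 2 / pos_states[None, :]
                var1 = max(float(np.sum(w * resid2) / wsum), 1.05 * mu1)
                new_emission = EmissionModel(mu1, var1, self.s_max)
            else:
                new_emission = emission
            return new_emission, new_transition, new_initial

        log_b = emission.log_pmf_matrix(x)
        gamma, xi_sum, ll = self._forward_backward(log_b, transition, initial)
        history: list[float] = [ll]
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            cand_em, cand_tr, cand_in = m_step(gamma, xi_sum)
            # the tied-moment M-step is moment matching, not the exact
            # maximiser; safeguard with step-halving so the likelihood
            # never decreases
            alpha = 1.0
            accepted = False
            for _ in range(8):
                em_t = EmissionModel(
                    (1 - alpha) * emission.mu1 + alpha * cand_em.mu1,
                    max(
                        (1 - alpha) * emission.var1 + alpha * cand_em.var1,
                        1.05 * ((1 - alpha) * emission.mu1 + alpha * cand_em.mu1),
                    ),
                    self.s_max,
                )
                tr_t = (1 - alpha) * transition + alpha * cand_tr
                in_t = (1 - alpha) * initial + alpha * cand_in
                log_b_t = em_t.log_pmf_matrix(x)
                gamma_t, xi_t, ll_t = self._forward_backward(log_b_t, tr_t, in_t)
                if ll_t >= ll - 1e-9 * abs(ll):
                    accepted = True
                    break
                alpha /= 2
            if not accepted:
                converged = True
                break
            emission, transition, initial = em_t, tr_t, in_t
            gamma, xi_sum = gamma_t, xi_t
            improvement = ll_t - ll
            ll = ll_t
            history.append(ll)
            if abs(improvement) < tol * abs(ll):
                converged = True
                break

        if decode == "viterbi":
            states = self._viterbi(emission.log_pmf_matrix(x), transition, initial)
        elif decode == "posterior":
            prio = _state_priority(self.s_max)
            # argmax over priority-ordered columns: first max wins a tie
            states = prio[np.argmax(gamma[:, prio], axis=1)]
        else:
            raise ValueError("decode must be 'posterior' or 'viterbi'")

        return CopyNumberHMMResults(
            model=self,
            emission=emission,
            transition=transition,
            initial=initial,
            log_likelihood=ll,
            llf_history=history,
            posteriors=gamma,
            states=states.astype(np.int64),
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class CopyNumberHMMResults:
    """Fitted HMM parameters, posteriors and decoded copy-number states."""

    model: CopyNumberHMM
    emission: EmissionModel | None
    transition: np.ndarray
    initial: np.ndarray
    log_likelihood: float
    llf_history: list[float]
    posteriors: np.ndarray
    states: np.ndarray
    converged: bool
    n_iter: int
    flags: list[str] = field(default_factory=list)

    @property
    def s_max(self) -> int:
        return self.model.s_max

    @property
    def grid(self) -> BinGrid | None:
        return self.model.grid

    def called_posterior(self) -> np.ndarray:
        """Posterior probability of the called state, per bin."""
        return self.posteriors[np.arange(len(self.states)), self.states]

    def segments(self, grid: BinGrid | None = None) -> pd.DataFrame:
        """Maximal constant-state runs, never crossing chromosome boundaries.

        Returns a frame with columns ``chrom, start_bin, end_bin, start,
        end, state`` where bin ranges are half-open in grid order.
        """
        grid = grid if grid is not None else self.grid
        if grid is None:
            raise ValueError("a BinGrid is required for segment decoding")
        return decode_segments(self, grid)

    def n_segments(self, grid: BinGrid | None = None) -> int:
        return len(self.segments(grid))

    def profile(self, grid: BinGrid | None = None) -> pd.DataFrame:
        """Per-bin BED-like profile: chrom, start, end, state, posterior."""
        grid = grid if grid is not None else self.grid
        if grid is None:
            raise ValueError("a BinGrid is required for the profile")
        return pd.DataFrame(
            {
                "chrom": grid.df["chrom"],
                "start": grid.df["start"],
                "end": grid.df["end"],
                "state": self.states,
                "posterior": self.called_posterior(),
            }
        )

    def summary(self) -> str:
        lines = [
            "Copy-number HMM fit",
            "===================",
            f"bins:            {len(self.states)}",
            f"states:          0..{self.s_max}",
        ]
        if self.emission is not None:
            lines += [
                f"mu1 (monosomy):  {self.emission.mu1:.4f}",
                f"var1:            {self.emission.var1:.4f}",
                f"NB p (shared):   {self.emission.nb_p:.6f}",
            ]
        lines += [
            f"log-likelihood:  {self.log_likelihood:.4f}",
            f"iterations:      {self.n_iter}",
            f"converged:       {self.converged}",
        ]
        counts = np.bincount(self.states, minlength=self.s_max + 1)
        occupied = ", ".join(
            f"{s}:{c}" for s, c in enumerate(counts) if c > 0
        )
        lines.append(f"bins per state:  {occupied}")
        return "\n".join(lines)


def fit_copy_number_hmm(
    counts: Sequence[float] | np.ndarray,
    grid: BinGrid | None = None,
    s_max: int = 10,
    max_iter: int = 200,
    tol: float = 1e-4,
    decode: str = "posterior",
) -> CopyNumberHMMResults:
    """Convenience wrapper: build a :class:`CopyNumberHMM` and fit it."""
    return CopyNumberHMM(counts, grid=grid, s_max=s_max).fit(
        max_iter=max_iter, tol=tol, decode=decode
    )


def decode_segments(fit: CopyNumberHMMResults, grid: BinGrid) -> pd.DataFrame:
    """Split decoded states into maximal constant-state runs per chromosome."""
    states = fit.states
    if len(states) != grid.n_bins:
        raise ValueError("fit does not match grid")
    rows = []
    for chrom, sl in grid.chrom_slices().items():
        s = states[sl]
        if len(s) == 0:
            continue
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(s)]])
        for a, b in zip(starts, ends):
            rows.append(
                {
                    "chrom": chrom,
                    "start_bin": sl.start + int(a),
                    "end_bin": sl.start + int(b),
                    "start": int(grid.df["start"].iloc[sl.start + a]),
                    "end": int(grid.df["end"].iloc[sl.start + b - 1]),
                    "state": int(s[a]),
                }
            )
    return pd.DataFrame(rows)
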