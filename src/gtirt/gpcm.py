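"""Generalized partial credit model (GPCM) kernel.

For an item k with discrimination ``alpha_k > 0`` and step thresholds
``delta_k1 .. delta_kM`` (``delta_k0 == 0`` implicitly), the probability of a
response in category m given a latent occasion score theta is

    P(Y = m | theta) = exp( sum_{h<=m} alpha_k (theta - delta_kh) )
                       / sum_{y=0}^{M} exp( sum_{h<=y} alpha_k (theta - delta_kh) )

with the empty sum for m = 0 equal to zero.  All probability computation is
done in log-space with max-subtraction so that the exponent sums cannot
overflow for extreme theta.  Thresholds are stored unordered: the model does
not require ordered steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GpcmItem",
    "GpcmItemBank",
    "category_probabilities",
    "log_likelihood",
    "expected_score",
    "sample_response",
]


@dataclass(frozen=True)
class GpcmItem:
    """A single GPCM item: discrimination and M_k step thresholds."""

    alpha: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError("discrimination alpha must be positive")
        t = tuple(float(x) for x in np.atleast_1d(self.thresholds))
        if len(t) < 1 or not np.all(np.isfinite(t)):
            raise ValueError("thresholds must be a non-empty finite vector")
        object.__setattr__(self, "thresholds", t)

    @property
    def n_steps(self) -> int:
        """M_k: number of steps, i.e. categories minus one."""
        return len(self.thresholds)


class GpcmItemBank:
    """Ordered collection of GPCM items with padded parameter arrays.

    Attributes with array shape (K,) or (K, M_max): ``alpha``, ``delta``
    (NaN-padded), ``n_steps``.  ``cum_delta[k, m] = sum_{h<=m} delta_kh`` is
    precomputed for the vectorized likelihood kernels.
    """

    def __init__(self, items):
        self.items = [
            it if isinstance(it, GpcmItem) else GpcmItem(*it) for it in items
        ]
        if not self.items:
            raise ValueError("item bank must contain at least one item")
        self._rebuild()

    def _rebuild(self) -> None:
        K = len(self.items)
        self.n_steps = np.array([it.n_steps for it in self.items], dtype=int)
        M = int(self.n_steps.max())
        self.alpha = np.array([it.alpha for it in self.items], dtype=float)
        self.delta = np.full((K, M), np.nan)
        for k, it in enumerate(self.items):
            self.delta[k, : it.n_steps] = it.thresholds
        self._refresh_cache()

    def _refresh_cache(self) -> None:
        K, M = self.delta.shape
        cum = np.zeros((K, M + 1))
        cum[:, 1:] = np.nancumsum(self.delta, axis=1)
        self.cum_delta = cum
        # valid[k, m] is True for categories 0..M_k
        self.valid = np.arange(M + 1)[None, :] <= self.n_steps[:, None]

    def set_parameters(self, alpha: np.ndarray, delta: np.ndarray) -> None:
        """Replace parameters in place (sampler hot path); shapes must match."""
        self.alpha = np.asarray(alpha, dtype=float).copy()
        self.delta = np.asarray(delta, dtype=float).copy()
        self._refresh_cache()

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, k: int) -> GpcmItem:
        steps = self.delta[k, : self.n_steps[k]]
        return GpcmItem(float(self.alpha[k]), tuple(steps))

    # -- vectorized kernels (sampler hot path) ----------------------------

    def log_prob_table(self, theta: np.ndarray) -> np.ndarray:
        """Log category probabilities, shape (n, K, M_max + 1).

        Entries for categories above an item's M_k are -inf.
        """
        theta = np.asarray(theta, dtype=float)
        m = np.arange(self.cum_delta.shape[1])
        A = self.alpha[:, None] * m[None, :]            # (K, M+1)
        B = self.alpha[:, None] * self.cum_delta        # (K, M+1)
        S = theta[:, None, None] * A[None] - B[None]    # (n, K, M+1)
        S = np.where(self.valid[None], S, -np.inf)
        Smax = S.max(axis=2, keepdims=True)
        lse = Smax[..., 0] + np.log(
            np.exp(S - Smax).sum(axis=2)
        )
        return S - lse[..., None]

    def record_log_prob(self, theta: np.ndarray, resp_mat: np.ndarray) -> np.ndarray:
        """Per-cell log likelihood, shape (n, K); 0 where resp_mat == -1."""
        lp = self.log_prob_table(theta)
        r = np.clip(resp_mat, 0, None)
        out = np.take_along_axis(lp, r[:, :, None], axis=2)[:, :, 0]
        return np.where(resp_mat >= 0, out, 0.0)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        M = self.delta.shape[1]
        data = {"item": np.arange(len(self)), "alpha": self.alpha}
        for h in range(M):
            data[f"delta_{h + 1}"] = self.delta[:, h]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GpcmItemBank":
        dcols = sorted(
            (c for c in frame.columns if c.startswith("delta_")),
            key=lambda c: int(c.split("_")[1]),
        )
        items = []
        for _, row in frame.sort_values("item").iterrows():
            steps = [row[c] for c in dcols if np.isfinite(row[c])]
            items.append(GpcmItem(float(row["alpha"]), tuple(steps)))
        return cls(items)

    @classmethod
    def read_csv(cls, path) -> "GpcmItemBank | dict[str, GpcmItemBank]":
        """Read a bank CSV; a ``group`` column yields one bank per group."""
        frame = pd.read_csv(path)
        if "group" in frame.columns:
            return {
                str(g): cls.from_frame(sub) for g, sub in frame.groupby("group")
            }
        return cls.from_frame(frame)


def category_probabilities(theta: float, item: GpcmItem) -> np.ndarray:
    """Probability vector over categories 0..M_k at latent score theta."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    cum = np.concatenate([[0.0], np.cumsum(item.thresholds)])
    m = np.arange(item.n_steps + 1)
    s = item.alpha * (m * theta - cum)
    s -= s.max()
    p = np.exp(s)
    return p / p.sum()


def log_likelihood(responses, theta: float, bank: GpcmItemBank) -> float:
    """Sum of log category probabilities for (item_id, category) pairs.

    ``responses`` is an iterable of (item_id, category); items not present
    are treated as missing and simply skipped.
    """
    total = 0.0
    for item_id, m in responses:
        if not 0 <= item_id < len(bank):
            raise KeyError(f"item {item_id} not in bank")
        p = category_probabilities(theta, bank[item_id])
        if not 0 <= m < len(p):
            raise ValueError(f"category {m} invalid for item {item_id}")
        total += float(np.log(p[m]))
    return total


def expected_score(theta: float, item: GpcmItem) -> float:
    """E(Y | theta) = sum_m m * P(Y = m | theta), in [0, M_k]."""
    p = category_probabilities(theta, item)
    return float(np.dot(np.arange(len(p)), p))


def sample_response(theta: float, item: GpcmItem, rng: np.random.Generator) -> int:
    """Draw one response category from the GPCM at theta."""
    p = category_probabilities(theta, item)
    return int(rng.choice(len(p), p=p))
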