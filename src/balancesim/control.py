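"""Three-way delayed feedback controller.

Every muscle's excitation is the clipped sum of three contributions plus a
small baseline tone:

* a stretch reflex ``u_L = K_L (l(t - t_Dm) - l_0)`` on the muscle's own
  delayed normalized fiber length (muscle-spindle pathway),
* antagonist force feedback ``u_F = K_F F̂(t - t_Dm)`` on the delayed
  normalized force of the muscle's antagonist(s) (co-contraction pathway),
* whole-body COM feedback
  ``u_COM = K_CP (p_foot - p_com)(t - t_D) + K_CV (ṗ_foot - ṗ_com)(t - t_D)``
  on the delayed anterior-posterior offset between the feet COM and the
  whole-body COM (vestibular/supraspinal pathway).

Per-muscle monosynaptic delays t_Dm lie in 35-100 ms; the COM feedback delay
t_D is the experimental variable (100/150/200 ms for healthy, aging and
severely delayed sensing).  Parameters are shared bilaterally; the COM error
is routed to the 18 muscles through per-muscle signed gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .muscle import UNIQUE_MUSCLES

U_BASE_DEFAULT = 0.01

#: directed force-feedback groups (receivers <- sources), one gain each;
#: the three agonist/antagonist pairs and their reverse mappings.
FORCE_GROUPS = (
    (("IL",), ("GM", "HM")),
    (("GM", "HM"), ("IL",)),
    (("RF", "VAS"), ("HM", "BF")),
    (("HM", "BF"), ("RF", "VAS")),
    (("TA",), ("GAS", "SOL")),
    (("GAS", "SOL"), ("TA",)),
)

#: agonist/antagonist pairs used for the co-contraction index
CCI_PAIRS = (("VAS", "HM"), ("RF", "HM"), ("IL", "HM"),
             ("TA", "GAS"), ("TA", "SOL"))

# optimizer box bounds per parameter family
BOUNDS = {"K_L": (0.0, 10.0), "l_0": (0.5, 1.5),
          "K_CP": (-20.0, 20.0), "K_CV": (-20.0, 20.0), "K_F": (0.0, 5.0)}

N_PARAMS = 4 * len(UNIQUE_MUSCLES) + len(FORCE_GROUPS)  # 42


class DelayLine:
    """Exact transport delay on a uniformly sampled signal.

    The delay must be (close to) an integer multiple of the sample step;
    queries earlier than the first stored sample return the prefill value
    (by default the t = 0 sample, i.e. the steady pre-perturbation signal).
    """

    def __init__(self, delay: float, dt: float, prefill: float | None = None):
        if delay < 0:
            raise ValueError("delay must be >= 0")
        steps = delay / dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("delay must be an integer multiple of dt")
        self.steps = int(round(steps))
        self.dt = dt
        self._buf: list[float] = []
        self._prefill = prefill

    def push(self, value: float) -> None:
        self._buf.append(float(value))

    def delayed(self) -> float:
        """Signal value ``delay`` seconds before the most recent push."""
        if not self._buf:
            raise ValueError("no samples pushed yet")
        idx = len(self._buf) - 1 - self.steps
        if idx < 0:
            return self._prefill if self._prefill is not None else self._buf[0]
        return self._buf[idx]


@dataclass(frozen=True)
class AntagonistPairs:
    """Mutual force-feedback wiring; defaults to the standard three pairs."""

    groups: tuple = FORCE_GROUPS

    def __post_init__(self) -> None:
        for recv, src in self.groups:
            for m in recv + src:
                if m not in UNIQUE_MUSCLES:
                    raise ValueError(f"unknown muscle {m}")
        # mutuality: if A's force drives B, B's force must drive A
        drives = {(s, r) for recv, srcs in self.groups
                  for r in recv for s in srcs}
        for s, r in drives:
            if (r, s) not in drives:
                raise ValueError(f"pairing not mutual: {s}->{r}")


@dataclass(frozen=True)
class ReflexParams:
    """All optimizable controller constants, shared bilaterally.

    Arrays are ordered like ``UNIQUE_MUSCLES``; ``K_F`` follows
    ``FORCE_GROUPS``.  ``com_delay`` (t_D) and the per-muscle reflex delays
    are fixed, not optimized.
    """

    K_L: np.ndarray = field(default_factory=lambda: np.zeros(9))
    l_0: np.ndarray = field(default_factory=lambda: np.ones(9))
    K_CP: np.ndarray = field(default_factory=lambda: np.zeros(9))
    K_CV: np.ndarray = field(default_factory=lambda: np.zeros(9))
    K_F: np.ndarray = field(default_factory=lambda: np.zeros(6))
    com_delay: float = 0.100
    u_base: float = U_BASE_DEFAULT

    def __post_init__(self) -> None:
        for name, n in (("K_L", 9), ("l_0", 9), ("K_CP", 9), ("K_CV", 9),
                        ("K_F", 6)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have {n} entries")
            object.__setattr__(self, name, arr)
        if np.any(self.K_L < 0) or np.any(self.K_F < 0):
            raise ValueError("K_L and K_F must be non-negative")
        if self.com_delay < 0:
            raise ValueError("com_delay must be >= 0")

    # -- flat-vector genome -------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.K_L, self.l_0, self.K_CP, self.K_CV,
                               self.K_F])

    @classmethod
    def from_vector(cls, x: np.ndarray, com_delay: float = 0.100,
                    u_base: float = U_BASE_DEFAULT) -> "ReflexParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters")
        return cls(K_L=x[0:9].copy(), l_0=x[9:18].copy(), K_CP=x[18:27].copy(),
                   K_CV=x[27:36].copy(), K_F=x[36:42].copy(),
                   com_delay=com_delay, u_base=u_base)

    @staticmethod
    def vector_bounds() -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name, n in (("K_L", 9), ("l_0", 9), ("K_CP", 9), ("K_CV", 9),
                        ("K_F", 6)):
            lo += [BOUNDS[name][0]] * n
            hi += [BOUNDS[name][1]] * n
        return np.array(lo), np.array(hi)

    def with_delay(self, com_delay: float) -> "ReflexParams":
        return replace(self, com_delay=com_delay)

    # -- per-muscle (18) expansions ----------------------------------------
    def expand(self, attr: str) -> np.ndarray:
        """Bilateral 18-muscle array from the 9 shared values."""
        v = getattr(self, attr)
        return np.concatenate([v, v])

    def force_gain_matrix(self) -> np.ndarray:
        """(18, 18) matrix G with u_F = G @ F̂_delayed, same-side wiring."""
        G = np.zeros((18, 18))
        idx = {m: i for i, m in enumerate(UNIQUE_MUSCLES)}
        for g, (recv, src) in enumerate(FORCE_GROUPS):
            for r in recv:
                for s in src:
                    for off in (0, 9):  # right leg, left leg
                        G[idx[r] + off, idx[s] + off] += self.K_F[g]
        return G

    # -- text serialization (the optimizer's genome file) -------------------
    def to_text(self) -> str:
        lines = [f"com_delay = {float(self.com_delay)!r}",
                 f"u_base = {float(self.u_base)!r}"]
        for fam, names in (("K_L", UNIQUE_MUSCLES), ("l_0", UNIQUE_MUSCLES),
                           ("K_CP", UNIQUE_MUSCLES), ("K_CV", UNIQUE_MUSCLES)):
            arr = getattr(self, fam)
            lines += [f"{fam}.{n} = {float(v)!r}" for n, v in zip(names, arr)]
        lines += [f"K_F.{g} = {float(v)!r}" for g, v in enumerate(self.K_F)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ReflexParams":
        vals = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            vals[key.strip()] = float(raw.strip())
        idx = {m: i for i, m in enumerate(UNIQUE_MUSCLES)}
        kw = {"com_delay": vals["com_delay"], "u_base": vals["u_base"]}
        for fam in ("K_L", "l_0", "K_CP", "K_CV"):
            arr = np.zeros(9)
            for n, i in idx.items():
                arr[i] = vals[f"{fam}.{n}"]
            kw[fam] = arr
        kw["K_F"] = np.array([vals[f"K_F.{g}"] for g in range(6)])
        return cls(**kw)


# ---------------------------------------------------------------------------
# the three laws (scalar reference forms; the kernel mirrors them)
# ---------------------------------------------------------------------------

def length_reflex(K_L: float, l_delayed: float, l_0: float) -> float:
    """Stretch-reflex contribution K_L (l(t - t_Dm) - l_0), unclipped."""
    if l_delayed <= 0:
        raise ValueError("normalized length must be positive")
    return K_L * (l_delayed - l_0)


def force_feedback(K_F: float, F_antagonist_delayed) -> float:
    """Force-feedback contribution K_F * sum of delayed normalized
    antagonist forces (forces normalized by each antagonist's f_max)."""
    F = np.atleast_1d(np.asarray(F_antagonist_delayed, dtype=float))
    if np.any(F < 0):
        raise ValueError("normalized forces must be >= 0")
    return K_F * float(F.sum())

def com_feedback(K_CP: float, K_CV: float, dp_delayed: float,
                 dv_delayed: float) -> float:
    """COM-feedback contribution on the delayed foot-minus-body COM offset."""
    return K_CP * dp_delayed + K_CV * dv_delayed


def total_excitation(u_L: float, u_F: float, u_COM: float,
                     u_base: float = U_BASE_DEFAULT) -> float:
    """Combine the three contributions with baseline tone; clip to [0, 1]."""
    return float(np.clip(u_L + u_F + u_COM + u_base, 0.0, 1.0))


@dataclass
class ControlHistory:
    """Uniformly sampled signal history the controller reads from.

    Rows are integration steps from t = 0; values before t = 0 take the
    first row (the model starts at rest, so this is the steady
    pre-perturbation signal).
    """

    dt: float
    l_norm: np.ndarray   # (n, 18)
    f_norm: np.ndarray   # (n, 18) forces normalized by f_max
    dp: np.ndarray       # (n,) p_foot - p_com, AP
    dv: np.ndarray       # (n,)

    def sample(self, arr: np.ndarray, t: float, delay: float):
        k = int(round((t - delay) / self.dt))
        k = max(0, min(k, arr.shape[0] - 1))
        return arr[k]


def controller_step(model, history: ControlHistory, params: ReflexParams,
                    t: float) -> np.ndarray:
    """Evaluate all 18 muscle excitations at time t from the history.

    Reference implementation of the closed loop (the compiled kernel is the
    fast path); bilaterally shared parameters are applied to both legs.
    """
    KL = params.expand("K_L")
    L0 = params.expand("l_0")
    KCP = params.expand("K_CP")
    KCV = params.expand("K_CV")
    G = params.force_gain_matrix()
    dp = history.sample(history.dp, t, params.com_delay)
    dv = history.sample(history.dv, t, params.com_delay)
    exc = np.empty(18)
    for m, spec in enumerate(model.muscles):
        l_del = history.sample(history.l_norm, t, spec.reflex_delay)[m]
        f_del = history.sample(history.f_norm, t, spec.reflex_delay)
        u_L = length_reflex(KL[m], l_del, L0[m])
        u_F = float(G[m] @ f_del)
        u_C = com_feedback(KCP[m], KCV[m], dp, dv)
        exc[m] = total_excitation(u_L, u_F, u_C, params.u_base)
    return exc


def pack_controller(model, params: ReflexParams, dt: float):
    """Packed arrays for the compiled kernel."""
    tdm = np.array([m.reflex_delay for m in model.muscles])
    dm_steps = np.round(tdm / dt).astype(np.int64)
    dcom_steps = int(round(params.com_delay / dt))
    return (params.expand("K_L"), params.expand("l_0"),
            params.force_gain_matrix(), params.expand("K_CP"),
            params.expand("K_CV"), dm_steps, dcom_steps, params.u_base)
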