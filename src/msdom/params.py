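"""Parameter container for MSDOM parameterizations.

The same object serves as ground truth for the simulator and as the layout
definition the sampler's flat parameter vector is packed to / unpacked from,
so recovery tests can compare draw-by-draw against the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import likelihood as lk

FULL_STATES = ("day", "night", "daynight")
REDUCED_STATES = ("day", "night")


@dataclass
class MSDOMParams:
    """Coefficients of one MSDOM parameterization.

    Parameters
    ----------
    parameterization : {"full", "reduced"}
    occ_coefs : dict state -> 1-D coefficient vector
        Full: keys "day", "night", "daynight" (multinomial logit vs. the
        unoccupied reference state).  Reduced: keys "day", "night" (logits of
        the latent day-use / night-use propensities).
    occ_columns : dict state -> list of design-column names, same keys.
    det_day, det_night : length-2 arrays (intercept, winter effect) on the
        logit of per-occasion detection given true state 2 / 3.
    det_state4 : (3, 2) array, full model only.  Rows = observed day, night,
        day-and-night category (reference = not observed); columns =
        (intercept, winter effect) on the multinomial logit.
    shared_state4_season : if True the three state-4 winter effects collapse
        to the single shared value stored in row 0.
    """

    parameterization: str = "full"
    occ_coefs: dict = field(default_factory=dict)
    occ_columns: dict = field(default_factory=dict)
    det_day: np.ndarray = field(default_factory=lambda: np.zeros(2))
    det_night: np.ndarray = field(default_factory=lambda: np.zeros(2))
    det_state4: np.ndarray | None = None
    shared_state4_season: bool = False

    def __post_init__(self):
        if self.parameterization not in ("full", "reduced"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        self.det_day = np.asarray(self.det_day, dtype=float)
        self.det_night = np.asarray(self.det_night, dtype=float)
        self.occ_coefs = {k: np.asarray(v, dtype=float) for k, v in self.occ_coefs.items()}
        if not self.occ_columns:
            self.occ_columns = {k: [f"x{i}" for i in range(len(v))]
                                for k, v in self.occ_coefs.items()}
        if self.parameterization == "full" and self.det_state4 is None:
            self.det_state4 = np.zeros((3, 2))
        if self.det_state4 is not None:
            self.det_state4 = np.asarray(self.det_state4, dtype=float)
        for k, v in self.occ_coefs.items():
            if len(self.occ_columns[k]) != len(v):
                raise ValueError(f"occ_coefs[{k!r}] length does not match occ_columns")

    @property
    def states(self):
        return FULL_STATES if self.parameterization == "full" else REDUCED_STATES

    # -- link functions -----------------------------------------------------

    def occupancy_logprobs(self, X_by_state: dict) -> np.ndarray:
        """(n, 4) log state probabilities given per-state design matrices."""
        if self.parameterization == "full":
            return lk.occupancy_logprobs_full(
                [self.occ_coefs[s] for s in FULL_STATES],
                [X_by_state[s] for s in FULL_STATES],
            )
        return lk.occupancy_logprobs_reduced(
            self.occ_coefs["day"], self.occ_coefs["night"],
            X_by_state["day"], X_by_state["night"],
        )

    def occupancy_probs(self, X_by_state: dict) -> np.ndarray:
        return np.exp(self.occupancy_logprobs(X_by_state))

    def _state4_logits(self, winter: float) -> np.ndarray | None:
        if self.parameterization == "reduced":
            return None
        a = self.det_state4[:, 0]
        al = self.det_state4[:, 1]
        if self.shared_state4_season:
            al = np.full(3, self.det_state4[0, 1])
        return a + al * winter

    def observation_matrix(self, winter: float) -> np.ndarray:
        from scipy.special import expit
        p_day = expit(self.det_day[0] + self.det_day[1] * winter)
        p_night = expit(self.det_night[0] + self.det_night[1] * winter)
        return lk.observation_matrix(p_day, p_night, self._state4_logits(winter))

    # -- flat vector layout -------------------------------------------------

    def param_names(self) -> list[str]:
        names = []
        for s in self.states:
            names += [f"occ[{s}]:{c}" for c in self.occ_columns[s]]
        for s, arr in (("day", self.det_day), ("night", self.det_night)):
            names += [f"det[{s}]:intercept", f"det[{s}]:winter"]
        if self.parameterization == "full":
            for i, s in enumerate(FULL_STATES):
                names.append(f"det4[{s}]:intercept")
                if not self.shared_state4_season or i == 0:
                    suffix = "winter" if not self.shared_state4_season else "winter(shared)"
                    names.append(f"det4[{s}]:{suffix}")
        return names

    def flatten(self) -> np.ndarray:
        parts = [self.occ_coefs[s] for s in self.states]
        parts += [self.det_day, self.det_night]
        if self.parameterization == "full":
            if self.shared_state4_season:
                parts.append(np.array([self.det_state4[0, 0], self.det_state4[0, 1],
                                       self.det_state4[1, 0], self.det_state4[2, 0]]))
            else:
                parts.append(self.det_state4.ravel())
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, vec, template: "MSDOMParams") -> "MSDOMParams":
        """Unpack a flat vector using ``template``'s layout."""
        vec = np.asarray(vec, dtype=float)
        pos = 0
        occ = {}
        for s in template.states:
            k = len(template.occ_columns[s])
            occ[s] = vec[pos:pos + k]
            pos += k
        det_day = vec[pos:pos + 2]; pos += 2
        det_night = vec[pos:pos + 2]; pos += 2
        det_state4 = None
        if template.parameterization == "full":
            if template.shared_state4_season:
                a_d, al, a_n, a_dn = vec[pos:pos + 4]; pos += 4
                det_state4 = np.array([[a_d, al], [a_n, al], [a_dn, al]])
            else:
                det_state4 = vec[pos:pos + 6].reshape(3, 2); pos += 6
        if pos != len(vec):
            raise ValueError(f"vector length {len(vec)} does not match layout ({pos})")
        return cls(template.parameterization, occ, dict(template.occ_columns),
                   det_day, det_night, det_state4, template.shared_state4_season)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "parameterization": self.parameterization,
            "occ_coefs": {k: v.tolist() for k, v in self.occ_coefs.items()},
            "occ_columns": {k: list(v) for k, v in self.occ_columns.items()},
            "det_day": self.det_day.tolist(),
            "det_night": self.det_night.tolist(),
            "shared_state4_season": self.shared_state4_season,
        }
        if self.det_state4 is not None:
            d["det_state4"] = self.det_state4.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MSDOMParams":
        return cls(
            parameterization=d["parameterization"],
            occ_coefs={k: np.asarray(v) for k, v in d["occ_coefs"].items()},
            occ_columns={k: list(v) for k, v in d.get("occ_columns", {}).items()},
            det_day=np.asarray(d["det_day"]),
            det_night=np.asarray(d["det_night"]),
            det_state4=np.asarray(d["det_state4"]) if "det_state4" in d else None,
            shared_state4_season=d.get("shared_state4_season", False),
        )
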