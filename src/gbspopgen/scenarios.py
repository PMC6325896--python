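"""Demographic scenario templates for the boundary-group analysis.

Four scenarios describe how the Tajima-Tango group relates to its
neighbours N.JPN (northern Japanese), Honshu and Kyushu (both southern
Japanese), all descending from one ancestor that split at time t3 into a
northern and a southern lineage; a fifth two-deme template models the
split of a northern-Saga deme from a southern-Saga deme (the
"out of northern Kyushu" dating).  All populations keep constant diploid
effective sizes on their lineage (no growth, no bottlenecks); times are
in generations.

Backward in time the scenarios are:

I    Tajima-Tango merges into N.JPN at t1 (Tajima-Tango is a recent
     offshoot of N.JPN); Kyushu merges into Honshu at t2; N.JPN and
     Honshu merge into the ancestor at t3.
II   Tajima-Tango formed at t1 by admixture between N.JPN (fraction r)
     and Honshu (1-r); Kyushu merges into Honshu at t2; ancestor at t3.
III  N.JPN merges into Tajima-Tango at t1 (N.JPN originated in
     Tajima-Tango); Honshu merges into Kyushu at t2; Tajima-Tango and
     Kyushu merge into the ancestor at t3.
IV   Tajima-Tango formed at t1 by admixture between N.JPN (r) and
     Honshu (1-r); Honshu merges into Kyushu at t2; ancestor at t3.

Scenarios II and IV share the admixture origin of Tajima-Tango and
differ (like I vs III on the northern side) in which southern deme
carries the ancestral southern lineage between t2 and t3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .priors import Normal, PriorSet, Uniform

# event tuples, backward in time:
#   ("merge", time_param, source, dest)          all lineages source->dest
#   ("admix", time_param, source, dest1, dest2, rate_param)
#       each source lineage -> dest1 w.p. rate, else dest2


@dataclass
class DemographicScenario:
    """A parameterized topology of merges/admixtures over named demes."""

    name: str
    populations: list[str]          # sampled demes, in genotype order
    size_params: dict[str, str]     # deme -> size parameter name
    ancestor: str                   # unsampled root deme
    ancestor_size_param: str
    events: list[tuple]             # see module docstring
    time_params: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.time_params:
            self.time_params = sorted(
                {e[1] for e in self.events}
            )

    @property
    def all_demes(self) -> list[str]:
        return self.populations + [self.ancestor]

    def param_names(self) -> list[str]:
        names = [self.size_params[p] for p in self.populations]
        names.append(self.ancestor_size_param)
        names += [e[1] for e in self.events if e[1] not in names]
        # rate parameters
        names += [e[5] for e in self.events if e[0] == "admix"]
        return list(dict.fromkeys(names))

    # -- encodings -----------------------------------------------------
    def validate_draw(self, draw: dict[str, float]) -> None:
        missing = set(self.param_names()) - set(draw)
        if missing:
            raise ValueError(f"draw missing parameters: {sorted(missing)}")
        for e in self.events:
            if draw[e[1]] <= 0:
                raise ValueError(f"event time {e[1]} must be positive")
        for e in self.events:
            if e[0] == "admix" and not 0 < draw[e[5]] < 1:
                raise ValueError("admixture rate must be in (0,1)")

    def sizes(self, draw: dict[str, float]) -> np.ndarray:
        """Diploid sizes for all demes (sampled demes then ancestor)."""
        vals = [draw[self.size_params[p]] for p in self.populations]
        vals.append(draw[self.ancestor_size_param])
        return np.asarray(vals, dtype=float)

    def event_arrays(self, draw: dict[str, float]):
        """Encode events as flat arrays for the fast simulator.

        Returns (time, type, a, b, c, p) arrays sorted by time; type 0
        is merge (a->b), type 1 is admix (a->b w.p. p else a->c).
        """
        self.validate_draw(draw)
        deme_index = {d: k for k, d in enumerate(self.all_demes)}
        recs = []
        for order, e in enumerate(self.events):
            if e[0] == "merge":
                _, tname, src, dst = e
                recs.append(
                    (draw[tname], order, 0, deme_index[src],
                     deme_index[dst], 0, 0.0)
                )
            else:
                _, tname, src, d1, d2, rname = e
                recs.append(
                    (draw[tname], order, 1, deme_index[src],
                     deme_index[d1], deme_index[d2], draw[rname])
                )
        recs.sort()  # by time, then declaration order
        t = np.array([r[0] for r in recs])
        ty = np.array([r[2] for r in recs], dtype=np.int64)
        a = np.array([r[3] for r in recs], dtype=np.int64)
        b = np.array([r[4] for r in recs], dtype=np.int64)
        c = np.array([r[5] for r in recs], dtype=np.int64)
        p = np.array([r[6] for r in recs])
        return t, ty, a, b, c, p

    @staticmethod
    def msprime_name(deme: str) -> str:
        """Identifier-safe deme name for the msprime bridge."""
        out = re.sub(r"\W", "_", deme)
        return out if out[0].isalpha() or out[0] == "_" else f"p_{out}"

    def to_msprime(self, draw: dict[str, float]):
        """Equivalent msprime Demography (merges as mass migrations)."""
        import msprime

        self.validate_draw(draw)
        dem = msprime.Demography()
        sizes = self.sizes(draw)
        for deme, size in zip(self.all_demes, sizes):
            dem.add_population(
                name=self.msprime_name(deme), initial_size=size
            )
        t, ty, a, b, c, p = self.event_arrays(draw)
        names = [self.msprime_name(d) for d in self.all_demes]
        for k in range(len(t)):
            if ty[k] == 0:
                dem.add_mass_migration(
                    time=t[k], source=names[a[k]], dest=names[b[k]],
                    proportion=1.0,
                )
            else:
                dem.add_mass_migration(
                    time=t[k], source=names[a[k]], dest=names[b[k]],
                    proportion=p[k],
                )
                dem.add_mass_migration(
                    time=t[k], source=names[a[k]], dest=names[c[k]],
                    proportion=1.0,
                )
        dem.sort_events()
        return dem


# ----------------------------------------------------------------------
# Study templates
# ----------------------------------------------------------------------

NJPN, TT, KYUSHU, HONSHU, ANC = (
    "N.JPN", "Tajima-Tango", "Kyushu", "Honshu", "Ancestor",
)

_SIZE_PARAMS = {
    NJPN: "N_njpn",
    TT: "N_tajima_tango",
    KYUSHU: "N_kyushu",
    HONSHU: "N_honshu",
}


def _four_pop(name: str, events: list[tuple]) -> DemographicScenario:
    return DemographicScenario(
        name=name,
        populations=[NJPN, TT, KYUSHU, HONSHU],
        size_params=dict(_SIZE_PARAMS),
        ancestor=ANC,
        ancestor_size_param="N_ancestor",
        events=events,
    )


def build_scenarios() -> dict[str, DemographicScenario]:
    """The four boundary-group scenarios plus the two-deme split."""
    scenarios = {
        "I": _four_pop("I", [
            ("merge", "t1", TT, NJPN),
            ("merge", "t2", KYUSHU, HONSHU),
            ("merge", "t3", NJPN, ANC),
            ("merge", "t3", HONSHU, ANC),
        ]),
        "II": _four_pop("II", [
            ("admix", "t1", TT, NJPN, HONSHU, "r"),
            ("merge", "t2", KYUSHU, HONSHU),
            ("merge", "t3", NJPN, ANC),
            ("merge", "t3", HONSHU, ANC),
        ]),
        "III": _four_pop("III", [
            ("merge", "t1", NJPN, TT),
            ("merge", "t2", HONSHU, KYUSHU),
            ("merge", "t3", TT, ANC),
            ("merge", "t3", KYUSHU, ANC),
        ]),
        "IV": _four_pop("IV", [
            ("admix", "t1", TT, NJPN, HONSHU, "r"),
            ("merge", "t2", HONSHU, KYUSHU),
            ("merge", "t3", NJPN, ANC),
            ("merge", "t3", KYUSHU, ANC),
        ]),
        "out_of_nk": DemographicScenario(
            name="out_of_nk",
            populations=["S.Saga", "N.Saga"],
            size_params={"S.Saga": "N_s_saga", "N.Saga": "N_n_saga"},
            # after the split the remaining lineage coalesces within
            # S.Saga; the declared ancestor deme is never reached and
            # only formalizes the root
            ancestor="Ancestor",
            ancestor_size_param="N_s_saga",
            events=[
                ("merge", "t", "N.Saga", "S.Saga"),
            ],
        ),
    }
    return scenarios


def priors_tajima_tango(with_admixture: bool = True) -> PriorSet:
    """Priors for the four-deme scenarios (sizes and times in natural
    units: diploid individuals and generations at 1 year/generation)."""
    params = {
        "N_njpn": Normal(450_000, 500_000, 10_000, 3_000_000),
        "N_tajima_tango": Normal(600_000, 500_000, 10_000, 3_000_000),
        "N_kyushu": Normal(1_225_000, 500_000, 10_000, 3_000_000),
        "N_honshu": Normal(1_050_000, 500_000, 10_000, 3_000_000),
        "N_ancestor": Uniform(10_000, 30_000_000),
        "t1": Uniform(10, 4_000_000),
        "t2": Uniform(10, 4_000_000),
        "t3": Normal(4_000_000, 5_000_000, 1_000_000, 30_000_000),
    }
    if with_admixture:
        params["r"] = Uniform(0.001, 0.999)
    return PriorSet(
        params=params,
        constraints=["t3 > t2", "t3 > t1", "t2 >= t1"],
    )


def priors_out_of_nk() -> PriorSet:
    return PriorSet(
        params={
            "N_s_saga": Normal(1_300_000, 500_000, 10_000, 3_000_000),
            "N_n_saga": Normal(1_250_000, 500_000, 10_000, 3_000_000),
            "t": Uniform(1_000, 4_000_000),
        },
        constraints=[],
    )


def scenario_from_dict(payload: dict) -> DemographicScenario:
    """Build a scenario from a structured (YAML-friendly) mapping.

    Example::

        name: my-split
        populations: [A, B]
        size_params: {A: N_a, B: N_b}
        ancestor: ANC
        ancestor_size_param: N_anc
        events:
          - [merge, t1, B, A]
          - [admix, t0, B, A, ANC, r]
    """
    events = [tuple(e) for e in payload["events"]]
    for e in events:
        if e[0] not in ("merge", "admix"):
            raise ValueError(f"unknown event type {e[0]!r}")
        if (e[0] == "merge" and len(e) != 4) or (
                e[0] == "admix" and len(e) != 6):
            raise ValueError(f"malformed event {e!r}")
    return DemographicScenario(
        name=payload["name"],
        populations=list(payload["populations"]),
        size_params=dict(payload["size_params"]),
        ancestor=payload["ancestor"],
        ancestor_size_param=payload["ancestor_size_param"],
        events=events,
    )


def priors_from_dict(payload: dict) -> PriorSet:
    """Build a PriorSet from a structured mapping.

    Example::

        params:
          N_a: {type: normal, mean: 450000, sd: 500000,
                min: 10000, max: 3000000}
          t1:  {type: uniform, min: 10, max: 4000000}
        constraints: ["t1 < t2"]
    """
    import math

    params: dict[str, Uniform | Normal] = {}
    for name, spec in payload["params"].items():
        kind = spec["type"].lower()
        if kind == "uniform":
            params[name] = Uniform(spec["min"], spec["max"])
        elif kind == "normal":
            params[name] = Normal(
                spec["mean"], spec["sd"],
                spec.get("min", -math.inf), spec.get("max", math.inf),
            )
        else:
            raise ValueError(f"unknown prior type {kind!r} for {name}")
    return PriorSet(params=params,
                    constraints=list(payload.get("constraints", [])))


# display names used in reports, matching the field's notation
DISPLAY_NAMES = {
    "I": {"t1": "T_NJPN-TajimaTango", "t2": "T_Kyushu-Honshu",
          "t3": "T_NJPN-SJPN"},
    "II": {"t1": "T_admix", "t2": "T_Kyushu-Honshu", "t3": "T_NJPN-SJPN"},
    "III": {"t1": "T_NJPN-TajimaTango", "t2": "T_Kyushu-Honshu",
            "t3": "T_NJPN-SJPN"},
    "IV": {"t1": "T_admix", "t2": "T_Kyushu-Honshu", "t3": "T_NJPN-SJPN"},
    "out_of_nk": {"t": "T_SSaga-NSaga"},
}
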