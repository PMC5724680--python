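"""Individual participant data (IPD) containers and network configuration.

An IPD survival network is a set of randomised trials, each comparing two or
more treatments, with one row per patient: trial id, assigned treatment,
follow-up time and an event indicator (1 = death/event observed, 0 = right
censored).  The network configuration declares the treatments, the trial
*designs* (the treatment sets compared within a trial), the *basic contrasts*
that parameterise the network, optional inconsistency loops, and optional
treatment splits driven by a trial-level flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "MissingColumnError",
    "NonPositiveTimeError",
    "InvalidEventError",
    "UnknownTreatmentError",
    "Design",
    "NetworkSpec",
    "IPDDataset",
    "read_ipd",
    "write_ipd",
    "apply_splits",
    "read_network_config",
    "write_network_config",
]


class ValidationError(ValueError):
    """Base class for IPD / network validation failures."""


class MissingColumnError(ValidationError):
    pass


class NonPositiveTimeError(ValidationError):
    pass


class InvalidEventError(ValidationError):
    pass


class UnknownTreatmentError(ValidationError):
    pass


@dataclass(frozen=True)
class Design:
    """A trial design: the set of treatments compared, with its reference arm."""

    treatments: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if self.reference not in self.treatments:
            raise ValidationError(
                f"design reference {self.reference!r} not among its treatments "
                f"{self.treatments}"
            )
        if len(set(self.treatments)) < 2:
            raise ValidationError(f"design needs >=2 distinct treatments: {self.treatments}")

    def key(self) -> frozenset[str]:
        return frozenset(self.treatments)


@dataclass(frozen=True)
class NetworkSpec:
    """Treatments, designs and the basic-contrast coding of a treatment network.

    Parameters
    ----------
    treatments
        Ordered treatment labels; ``reference`` must be one of them.
    reference
        The network reference treatment (log hazard ratio 0 by convention).
    designs
        Declared trial designs.  Every trial's treatment set must match one.
    basic_contrasts
        The q independent comparisons ``(a, b)`` meaning "effect of b vs a"
        that parameterise the network.  Defaults to reference-vs-each-other
        treatment.  All other comparisons derive through the consistency
        equations.
    loops
        Treatment triples eligible for an inconsistency parameter.
    splits
        Map ``(treatment, flag) -> augmented label`` used by
        :func:`apply_splits` to treat e.g. short- and long-cycle variants of
        one therapy as separate treatments.
    """

    treatments: tuple[str, ...]
    reference: str
    designs: tuple[Design, ...]
    basic_contrasts: tuple[tuple[str, str], ...] = ()
    loops: tuple[tuple[str, str, str], ...] = ()
    splits: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.reference not in self.treatments:
            raise ValidationError(f"reference {self.reference!r} not a declared treatment")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValidationError("duplicate treatment labels")
        if not self.basic_contrasts:
            object.__setattr__(
                self,
                "basic_contrasts",
                tuple((self.reference, t) for t in self.treatments if t != self.reference),
            )
        if len(self.basic_contrasts) != self.q:
            raise ValidationError(
                f"expected q={self.q} basic contrasts, got {len(self.basic_contrasts)}"
            )
        for a, b in self.basic_contrasts:
            for t in (a, b):
                if t not in self.treatments:
                    raise ValidationError(f"basic contrast references unknown treatment {t!r}")
        for d in self.designs:
            for t in d.treatments:
                if t not in self.treatments:
                    raise ValidationError(f"design references unknown treatment {t!r}")
            # must be expressible in the basic contrasts
            for t in d.treatments:
                self.expression(t)
        in_designs = {t for d in self.designs for t in d.treatments}
        for loop in self.loops:
            if len(set(loop)) != 3:
                raise ValidationError(f"loop must have 3 distinct treatments: {loop}")
            for t in loop:
                if t not in in_designs:
                    raise ValidationError(f"loop treatment {t!r} not present in any design")

    @property
    def q(self) -> int:
        return len(self.treatments) - 1

    def design_for(self, treatment_set) -> Design:
        key = frozenset(treatment_set)
        for d in self.designs:
            if d.key() == key:
                return d
        raise ValidationError(f"treatment set {sorted(key)} matches no declared design")

    def expression(self, treatment: str) -> np.ndarray:
        """Coefficients expressing ``treatment``'s effect vs the network
        reference as a linear combination of the basic contrasts.

        Derived by walking the graph whose edges are the basic contrasts: the
        consistency equations say effect(b vs a) = v(b) - v(a) where v maps
        treatments to basic-parameter combinations with v(reference) = 0.
        """
        v = {self.reference: np.zeros(self.q)}
        frontier = [self.reference]
        while frontier:
            cur = frontier.pop()
            for k, (a, b) in enumerate(self.basic_contrasts):
                e = np.zeros(self.q)
                e[k] = 1.0
                if a == cur and b not in v:
                    v[b] = v[cur] + e
                    frontier.append(b)
                elif b == cur and a not in v:
                    v[a] = v[cur] - e
                    frontier.append(a)
        if treatment not in v:
            raise ValidationError(
                f"treatment {treatment!r} not expressible in the basic contrasts"
            )
        return v[treatment]

    def contrast_labels(self) -> list[str]:
        return [f"{a}:{b}" for a, b in self.basic_contrasts]


_REQUIRED = ("trial", "treatment", "time", "event")


@dataclass(frozen=True)
class IPDDataset:
    """Patient-level survival records for a network of trials.

    Backed by a :class:`pandas.DataFrame` with columns
    ``patient_id, trial, treatment, time, event``.  Times must be positive
    (the models work on ln time) and are never rescaled; knot locations are
    therefore unit-dependent and the caller must keep units consistent.
    """

    df: pd.DataFrame

    def __post_init__(self):
        for col in _REQUIRED:
            if col not in self.df.columns:
                raise MissingColumnError(f"missing required column {col!r}")
        if "patient_id" not in self.df.columns:
            df = self.df.copy()
            df.insert(0, "patient_id", np.arange(len(df)))
            object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def trial_ids(self) -> list:
        return list(dict.fromkeys(self.df["trial"]))

    def trial(self, trial_id) -> "IPDDataset":
        return IPDDataset(self.df[self.df["trial"] == trial_id].reset_index(drop=True))

    def validate(self, network: NetworkSpec | None = None) -> "IPDDataset":
        df = self.df
        bad = df.index[~(pd.to_numeric(df["time"], errors="coerce") > 0)]
        if len(bad):
            raise NonPositiveTimeError(f"non-positive time at row {bad[0]}")
        ev = pd.to_numeric(df["event"], errors="coerce")
        bad = df.index[~ev.isin([0, 1])]
        if len(bad):
            raise InvalidEventError(f"event outside {{0,1}} at row {bad[0]}")
        if network is not None:
            known = set(network.treatments)
            bad = df.index[~df["treatment"].isin(known)]
            if len(bad):
                raise UnknownTreatmentError(
                    f"treatment {df.loc[bad[0], 'treatment']!r} at row {bad[0]} "
                    "absent from network"
                )
        for tid, grp in df.groupby("trial", sort=False):
            arms = set(grp["treatment"])
            if len(arms) < 2:
                raise ValidationError(f"trial {tid!r} has <2 distinct treatments")
            if not (pd.to_numeric(grp["event"]) == 1).any():
                raise ValidationError(f"trial {tid!r} has no uncensored event")
            if network is not None:
                network.design_for(arms)
        return self


def read_ipd(path, network: NetworkSpec | None = None) -> IPDDataset:
    """Read a ``trial,treatment,time,event`` CSV and validate it."""
    df = pd.read_csv(path, comment="#")
    for col in _REQUIRED:
        if col not in df.columns:
            raise MissingColumnError(f"missing required column {col!r} in {path}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return IPDDataset(df).validate(network)


def write_ipd(data: IPDDataset, path) -> None:
    data.df.to_csv(path, index=False)


def apply_splits(data: IPDDataset, network: NetworkSpec, flags: dict) -> IPDDataset:
    """Relabel a treatment in flagged trials with its augmented label.

    ``flags`` maps trial_id -> flag value; ``network.splits`` maps
    ``(treatment, flag)`` to the augmented treatment label.  Trials without a
    flag (or whose flag matches no split) are unchanged; record count is
    preserved.
    """
    known = set(data.trial_ids)
    for tid in flags:
        if tid not in known:
            raise ValidationError(f"split flag references unknown trial {tid!r}")
    if not flags or not network.splits:
        return data
    df = data.df.copy()
    for (trt, flag), new_label in network.splits.items():
        hit = [tid for tid, f in flags.items() if f == flag]
        for tid in hit:
            mask = (df["trial"] == tid) & (df["treatment"] == trt)
            if not mask.any():
                raise ValidationError(
                    f"trial {tid!r} flagged {flag!r} but has no {trt!r} arm to split"
                )
            df.loc[mask, "treatment"] = new_label
    return IPDDataset(df)


def _network_to_dict(network: NetworkSpec) -> dict:
    return {
        "treatments": list(network.treatments),
        "reference": network.reference,
        "designs": [
            {"treatments": list(d.treatments), "reference": d.reference}
            for d in network.designs
        ],
        "basic_contrasts": [list(c) for c in network.basic_contrasts],
        "loops": [list(l) for l in network.loops],
        "splits": [
            {"treatment": t, "flag": f, "label": lab}
            for (t, f), lab in network.splits.items()
        ],
    }


def _network_from_dict(d: dict) -> NetworkSpec:
    return NetworkSpec(
        treatments=tuple(d["treatments"]),
        reference=d["reference"],
        designs=tuple(
            Design(tuple(x["treatments"]), x["reference"]) for x in d.get("designs", [])
        ),
        basic_contrasts=tuple(tuple(c) for c in d.get("basic_contrasts", [])),
        loops=tuple(tuple(l) for l in d.get("loops", [])),
        splits={(x["treatment"], x["flag"]): x["label"] for x in d.get("splits", [])},
    )


def read_network_config(path) -> tuple[NetworkSpec, dict]:
    """Read a YAML run configuration.

    Returns the :class:`NetworkSpec` under the ``network`` key and the rest of
    the document (knots, priors, mcmc settings, ...) as a plain dict.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    network = _network_from_dict(doc["network"])
    options = {k: v for k, v in doc.items() if k != "network"}
    return network, options


def write_network_config(network: NetworkSpec, path, **options) -> None:
    doc = {"network": _network_to_dict(network), **options}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
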