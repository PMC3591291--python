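"""Kinetic parameters of the split-kinase system.

Units are fixed throughout the package: concentrations in µM, time in
seconds, first-order rates in 1/s and bimolecular rates in 1/(µM·s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict, Iterator, Mapping


@dataclass(frozen=True)
class ParameterSet(Mapping):
    """Rate constants and total concentrations of the basic split-kinase model.

    Defaults are the literature-derived base values for the
    CheA3/CheA4/CheY6 system of *Rhodobacter sphaeroides*:

    ========  =========================================================  =====
    field     meaning                                                    unit
    ========  =========================================================  =====
    k1        CheA3 + CheA4 association                                  1/(µM·s)
    k2        CheA3:CheA4 dissociation                                   1/s
    k3        ATP binding to CheA3:CheA4                                 1/(µM·s)
    k4        ATP release from CheA3:CheA4:ATP                           1/s
    k5        autophosphorylation k_cat — the *signal*                   1/s
    k6        CheA3-P -> CheY6 phosphotransfer                           1/(µM·s)
    k7        reverse phosphotransfer CheY6-P -> CheA3                   1/(µM·s)
    k8        CheY6-P autodephosphorylation                              1/s
    k9        CheA3 + CheY6-P phosphatase-complex association            1/(µM·s)
    k10       CheA3:CheY6-P dissociation                                 1/s
    k11       phosphatase k_cat (hydrolysis in the complex)              1/s
    A3_tot    total CheA3                                                µM
    A4_tot    total CheA4                                                µM
    Y6_tot    total CheY6                                                µM
    ATP       clamped ATP level                                          µM
    ========  =========================================================  =====

    ``k5`` is the signal and defaults to 0; analyses scan or schedule it.
    ``extras`` holds rate constants of variant architectures (k12…k20,
    k5_prime, k5_star, A2_tot, …) keyed by label.

    The object behaves as a read-only mapping from rate label to value so
    that reaction networks can resolve their rate labels directly.
    """

    k1: float = 100.0
    k2: float = 10.0
    k3: float = 1.0
    k4: float = 39.0
    k5: float = 0.0
    k6: float = 0.775
    k7: float = 0.00283
    k8: float = 0.169
    k9: float = 5.6
    k10: float = 0.04
    k11: float = 2.5
    A3_tot: float = 90.0
    A4_tot: float = 40.0
    Y6_tot: float = 225.0
    ATP: float = 1000.0
    extras: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "extras":
                continue
            v = getattr(self, f.name)
            if not (v >= 0.0):
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        for label, v in self.extras.items():
            if not (v >= 0.0):
                raise ValueError(f"extra rate {label} must be >= 0, got {v!r}")

    # Mapping interface -------------------------------------------------
    def __getitem__(self, label: str) -> float:
        if label in self.extras:
            return self.extras[label]
        try:
            return getattr(self, label)
        except AttributeError:
            raise KeyError(label) from None

    def __iter__(self) -> Iterator[str]:
        for f in fields(self):
            if f.name != "extras":
                yield f.name
        yield from self.extras

    def __len__(self) -> int:
        return len(fields(self)) - 1 + len(self.extras)

    # Convenience -------------------------------------------------------
    def with_(self, **overrides: float) -> "ParameterSet":
        """Return a copy with named fields or extra rates replaced."""
        known = {f.name for f in fields(self)}
        extra_over = {k: v for k, v in overrides.items() if k not in known}
        field_over = {k: v for k, v in overrides.items() if k in known}
        extras = dict(self.extras)
        extras.update(extra_over)
        return replace(self, extras=extras, **field_over)

    def scaled(self, label: str, ratio: float) -> "ParameterSet":
        """Return a copy with one parameter multiplied by ``ratio``."""
        return self.with_(**{label: self[label] * ratio})

    def to_dict(self) -> Dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "extras"}
        d.update(self.extras)
        return d
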