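"""Alternative model architectures of the split-kinase system.

Variants of the basic model relax its mechanistic assumptions:

* ``extra_phosphatase_complexes`` — the CheA3:CheA4 and CheA3:CheA4:ATP
  complexes also dephosphorylate CheY6-P (rates k12–k17);
* ``extra_phosphatase_A3p`` — phospho-CheA3 also acts as phosphatase
  (k18–k20);
* ``retained_complex`` — autophosphorylation does not release CheA4: the
  CheA3-P:CheA4 complex either releases CheA3-P (k5') or phosphotransfers
  to CheY6 directly;
* ``extra_kinase_A2`` — a second, monofunctional non-split kinase feeds
  background phosphorylation into CheY6 (k5*).

Every variant nests the basic model: zeroing the extra machinery
reproduces it reaction-for-reaction in flux.

The module also builds the minimal comparison architectures used for the
multistationarity screen: a non-split bifunctional kinase, a
monofunctional kinase with a dedicated phosphatase Z, and a
monofunctional split kinase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

from .network import BASIC_SPECIES, Reaction, ReactionNetwork, build_basic_network
from .parameters import ParameterSet

ARCHITECTURES = (
    "basic_split_bifunctional",
    "extra_phosphatase_complexes",
    "extra_phosphatase_A3p",
    "retained_complex",
    "extra_kinase_A2",
    "bifunctional_nonsplit",
    "monofunctional_plus_Z",
    "monofunctional_split",
)

#: defaults for supplementary rates whose tabulated values are unavailable;
#: every substituted default is echoed into run provenance records.
VARIANT_RATE_DEFAULTS: Dict[str, float] = {
    "k12": 0.0, "k13": 0.04, "k14": 0.0,     # A3A4 phosphatase on/off/cat
    "k15": 0.0, "k16": 0.04, "k17": 0.0,     # A3A4T phosphatase
    "k18": 0.0, "k19": 0.04, "k20": 0.0,     # A3p phosphatase
    "k5_prime": 0.1,                          # CheA3-P release from A3pA4, 1/s
    "k6_a3pa4": 0.775,                        # A3pA4 -> Y6 phosphotransfer
    "k5_star": 0.0,                           # CheA2 background autophosphorylation
    "k6_a2": 0.775,                           # CheA2-P -> Y6 phosphotransfer
    "A2_tot": 20.0,                           # µM
}
# off-rates k13/k16/k19 default to k10 (same complex-dissociation kinetics
# as the CheA3 phosphatase complex); phosphotransfer defaults reuse k6.


@dataclass(frozen=True)
class VariantSpec:
    """Architecture choice plus overrides of the supplementary rates.

    ``tie_complex_rates`` ties the two complex-phosphatase species together
    (k12=k15 and k14=k17), the convention used when their activity is
    swept as one set.  ``signal_coupling`` applies to the retained-complex
    variant: ``"independent"`` holds the release rate k5' fixed while the
    signal k5 is scanned, ``"coupled"`` ties the release rate to k5 so
    both move together.
    """

    architecture: str = "basic_split_bifunctional"
    rates: Mapping[str, float] = field(default_factory=dict)
    tie_complex_rates: bool = False
    signal_coupling: str = "independent"

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.signal_coupling not in ("independent", "coupled"):
            raise ValueError("signal_coupling must be 'independent' or 'coupled'")
        unknown = set(self.rates) - set(VARIANT_RATE_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown variant rates: {sorted(unknown)}")
        object.__setattr__(self, "rates", dict(self.rates))

    def resolved_rates(self) -> Dict[str, float]:
        r = dict(VARIANT_RATE_DEFAULTS)
        r.update(self.rates)
        if self.tie_complex_rates:
            r["k15"] = r["k12"]
            r["k17"] = r["k14"]
        for label, v in r.items():
            if v < 0:
                raise ValueError(f"variant rate {label} must be >= 0")
        return r

    def parameter_set(self, base: Optional[ParameterSet] = None) -> ParameterSet:
        """Base parameters with this variant's extra rates merged in."""
        base = base or ParameterSet()
        return base.with_(**self.resolved_rates())


def build_variant(base: Optional[ParameterSet], spec: VariantSpec) -> ReactionNetwork:
    """Reaction network for a variant architecture.

    The returned network resolves its extra rate labels against
    ``spec.parameter_set(base)``.  Comparison architectures
    (bifunctional_nonsplit, monofunctional_plus_Z, monofunctional_split)
    are delegated to :func:`build_architecture`.
    """
    arch = spec.architecture
    if arch in ("bifunctional_nonsplit", "monofunctional_plus_Z",
                "monofunctional_split"):
        net, _ = build_architecture(arch)
        return net
    base_net = build_basic_network(base)
    if arch == "basic_split_bifunctional":
        return base_net

    species = list(BASIC_SPECIES)
    reactions = list(base_net.reactions)

    if arch == "extra_phosphatase_complexes":
        species += ["A3A4Y6p", "A3A4TY6p"]
        reactions += [
            Reaction({"A3A4": 1, "Y6p": 1}, {"A3A4Y6p": 1}, "k12"),
            Reaction({"A3A4Y6p": 1}, {"A3A4": 1, "Y6p": 1}, "k13"),
            Reaction({"A3A4Y6p": 1}, {"A3A4": 1, "Y6": 1}, "k14"),
            Reaction({"A3A4T": 1, "Y6p": 1}, {"A3A4TY6p": 1}, "k15"),
            Reaction({"A3A4TY6p": 1}, {"A3A4T": 1, "Y6p": 1}, "k16"),
            Reaction({"A3A4TY6p": 1}, {"A3A4T": 1, "Y6": 1}, "k17"),
        ]
    elif arch == "extra_phosphatase_A3p":
        species += ["A3pY6p"]
        reactions += [
            Reaction({"A3p": 1, "Y6p": 1}, {"A3pY6p": 1}, "k18"),
            Reaction({"A3pY6p": 1}, {"A3p": 1, "Y6p": 1}, "k19"),
            Reaction({"A3pY6p": 1}, {"A3p": 1, "Y6": 1}, "k20"),
        ]
    elif arch == "retained_complex":
        species += ["A3pA4"]
        release_rate = "k5" if spec.signal_coupling == "coupled" else "k5_prime"
        reactions = [r for r in reactions if r.rate != "k5"]
        reactions += [
            Reaction({"A3A4T": 1}, {"A3pA4": 1}, "k5"),
            Reaction({"A3pA4": 1}, {"A3p": 1, "A4": 1}, release_rate),
            Reaction({"A3pA4": 1, "Y6": 1}, {"A3A4": 1, "Y6p": 1}, "k6_a3pa4"),
        ]
    elif arch == "extra_kinase_A2":
        species += ["A2", "A2p"]
        reactions += [
            Reaction({"A2": 1}, {"A2p": 1}, "k5_star"),
            Reaction({"A2p": 1, "Y6": 1}, {"A2": 1, "Y6p": 1}, "k6_a2"),
        ]
    return ReactionNetwork(
        species=tuple(species) + ("ATP",),
        reactions=reactions,
        clamped={"ATP": "ATP"},
        name=arch,
    )


#: generic rates for the minimal comparison architectures, mirroring the
#: magnitudes of the split-system base values
ARCHITECTURE_DEFAULTS: Dict[str, float] = {
    "kt": 0.775,      # phosphotransfer HK-P -> RR, 1/(µM·s)
    "kon": 5.6,       # phosphatase-complex association, 1/(µM·s)
    "koff": 0.04,     # phosphatase-complex dissociation, 1/s
    "kcat": 2.5,      # phosphatase catalytic rate, 1/s
    "kauto": 0.169,   # RR-P autodephosphorylation, 1/s
    "H_tot": 90.0,
    "R_tot": 225.0,
    "Z_tot": 10.0,
}


def build_architecture(
    arch: str,
    rates: Optional[Mapping[str, float]] = None,
) -> Tuple[ReactionNetwork, ParameterSet]:
    """Minimal mass-action scheme for one of the comparison architectures.

    Returns the network together with a parameter set resolving its rate
    labels (signal is always the label ``k5``).
    """
    if arch not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {arch!r}")
    if arch == "basic_split_bifunctional":
        return build_basic_network(), ParameterSet()
    if arch == "monofunctional_split":
        # free CheA3 keeps no phosphatase activity: the phosphatase-complex
        # reactions (k9/k10/k11) are absent structurally, which is the
        # dynamical equivalent of zeroing their rates in the basic model
        basic = build_basic_network()
        reactions = [r for r in basic.reactions if r.rate not in ("k9", "k10", "k11")]
        net = ReactionNetwork(
            species=tuple(s for s in BASIC_SPECIES if s != "A3Y6p") + ("ATP",),
            reactions=reactions,
            clamped={"ATP": "ATP"},
            name=arch,
        )
        return net, ParameterSet()

    merged = dict(ARCHITECTURE_DEFAULTS)
    merged.update(rates or {})
    params = ParameterSet().with_(**merged)

    if arch == "bifunctional_nonsplit":
        # unphosphorylated HK is the phosphatase of its own RR
        net = ReactionNetwork(
            species=("H", "Hp", "R", "Rp", "HRp"),
            reactions=[
                Reaction({"H": 1}, {"Hp": 1}, "k5"),
                Reaction({"Hp": 1, "R": 1}, {"H": 1, "Rp": 1}, "kt"),
                Reaction({"H": 1, "Rp": 1}, {"HRp": 1}, "kon"),
                Reaction({"HRp": 1}, {"H": 1, "Rp": 1}, "koff"),
                Reaction({"HRp": 1}, {"H": 1, "R": 1}, "kcat"),
                Reaction({"Rp": 1}, {"R": 1}, "kauto"),
            ],
            name=arch,
        )
    elif arch == "monofunctional_plus_Z":
        # dedicated auxiliary phosphatase Z (CheZ-like)
        net = ReactionNetwork(
            species=("H", "Hp", "R", "Rp", "Z", "ZRp"),
            reactions=[
                Reaction({"H": 1}, {"Hp": 1}, "k5"),
                Reaction({"Hp": 1, "R": 1}, {"H": 1, "Rp": 1}, "kt"),
                Reaction({"Z": 1, "Rp": 1}, {"ZRp": 1}, "kon"),
                Reaction({"ZRp": 1}, {"Z": 1, "Rp": 1}, "koff"),
                Reaction({"ZRp": 1}, {"Z": 1, "R": 1}, "kcat"),
                Reaction({"Rp": 1}, {"R": 1}, "kauto"),
            ],
            name=arch,
        )
    else:  # pragma: no cover - guarded above
        raise ValueError(arch)
    return net, params
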