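"""Energy-equivalence validation of a converted force field.

The desk-scale counterpart of a cross-engine single-point comparison: for a
battery of configurations covering every interaction-term class, the original
and the converted parameters are evaluated with two independent functional-
form implementations and the per-term energies are compared on the common
kJ/mol scale.  Exact conversion makes the two agree to floating-point
accuracy; any disagreement localizes the faulty term class immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .energy import (
    Configuration,
    EnergyReport,
    build_configuration,
    build_coordinates,
    compare,
)
from .fixups import MissingTermReport
from .model import ForceFieldSource, ResidueTopology
from .param_convert import GmxParameterSet


@dataclass
class ValidationOutcome:
    labels: list[str]
    reports: list[EnergyReport]
    passed: bool
    tolerance: float

    def summary(self) -> str:
        lines = []
        for label, rep in zip(self.labels, self.reports):
            worst_term, worst = rep.worst_term()
            status = "ok" if rep.passed else "FAIL " + ",".join(rep.failing_terms())
            lines.append(
                f"{label:<24s} worst rel. diff {worst:.3e} ({worst_term}) {status}"
            )
        return "\n".join(lines)


def make_validation_set(
    source: ForceFieldSource,
    seed: int,
    n_min: int = 20,
) -> list[tuple[str, Configuration]]:
    """Configurations spanning all retained multi-atom residues, replicated
    with fresh coordinates until at least ``n_min`` exist; single-atom
    residues (ions) are paired with the first oxygen-bearing molecule so the
    pair-specific LJ overrides are exercised."""
    rng = np.random.default_rng(seed)
    retained = source.retained_residues()
    multi = [r for r in retained.values() if len(r.atoms) > 1]
    ions = [r for r in retained.values() if len(r.atoms) == 1]
    configs: list[tuple[str, Configuration]] = []
    if not multi:
        return configs
    def partner_for(ion: ResidueTopology) -> ResidueTopology:
        # prefer a partner whose atoms trigger a pair-specific LJ override
        ion_type = ion.atoms[0].type
        for r in multi:
            if any(
                source.params.lookup_nbfix(ion_type, a.type) is not None
                for a in r.atoms
            ):
                return r
        return multi[0]

    replica = 0
    while len(configs) < n_min or replica < 2:
        for res in multi:
            crd = build_coordinates(res, source.params, rng)
            configs.append(
                (f"{res.name}#{replica}", build_configuration([res], [crd]))
            )
        for ion in ions:
            oxy = partner_for(ion)
            crd_m = build_coordinates(oxy, source.params, rng)
            crd_i = crd_m.mean(axis=0) + np.array([4.5, 0.0, 0.0]) + rng.normal(
                scale=0.3, size=3
            )
            configs.append(
                (
                    f"{ion.name}+{oxy.name}#{replica}",
                    build_configuration([ion, oxy], [crd_i[None, :], crd_m]),
                )
            )
        replica += 1
    return configs


def validate_equivalence(
    source: ForceFieldSource,
    gmx: GmxParameterSet,
    fixreport: Optional[MissingTermReport] = None,
    seed: int = 0,
    n_min: int = 20,
    tolerance: float = 1e-9,
) -> ValidationOutcome:
    dummies = (
        {d.types for d in fixreport.dummy_dihedraltypes} if fixreport else set()
    )
    labels: list[str] = []
    reports: list[EnergyReport] = []
    for label, cfg in make_validation_set(source, seed, n_min):
        labels.append(label)
        reports.append(
            compare(cfg, source.params, gmx, dummy_dihedrals=dummies,
                    tolerance=tolerance)
        )
    passed = bool(reports) and all(r.passed for r in reports)
    return ValidationOutcome(labels, reports, passed, tolerance)
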