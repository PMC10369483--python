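"""End-to-end conversion: parse -> merge -> convert -> perceive -> patch ->
termini -> hydrogen database -> fixups -> write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .charmm_io import merge_sources, parse_charmm_file, parse_config
from .fixups import MissingTermReport, check_completeness, run_fixups
from .geometry import PerceivedGeometry, perceive_residue
from .hdb import AttentionItem, HAddRule, generate_hdb
from .model import ConversionConfig, FFError, ForceFieldSource
from .param_convert import GmxParameterSet, convert_parameters
from .patching import TerminusEntry, build_terminus_entry, resolve_patched_residues
from .writers import FFPortLayout, write_port

log = logging.getLogger(__name__)


@dataclass
class ConversionResult:
    source: ForceFieldSource
    gmx: GmxParameterSet
    geometries: dict[str, PerceivedGeometry]
    termini: dict[str, dict[str, list[TerminusEntry]]]
    hdb_rules: dict[str, list[HAddRule]]
    attention: list[AttentionItem]
    fixreport: MissingTermReport
    layout: Optional[FFPortLayout]
    warnings: list[str] = field(default_factory=list)


def load_and_merge(config: ConversionConfig) -> ForceFieldSource:
    sources = [
        parse_charmm_file(path, dialect)
        for path, dialect, _cls in config.input_files
    ]
    return merge_sources(sources, config)


def run_conversion(
    config: ConversionConfig, outdir: Optional[str] = None
) -> ConversionResult:
    """The whole conversion; pass ``outdir`` to also write the force-field
    directory."""
    merged = load_and_merge(config)
    warnings = list(merged.warnings)

    # standalone patched residues join the model under their source class
    minted = resolve_patched_residues(merged, config.patched_residues)
    for (base_name, _patch, new_name), res in zip(
        config.patched_residues, minted.values()
    ):
        res.group = merged.residues[base_name].group
        merged.residues[new_name] = res

    # copyresidues: the same body under both names
    for src_name, alias in config.copyresidues:
        merged.residues[alias] = merged.residues[src_name].copy(alias)

    retained = merged.retained_residues()
    geometries = {
        name: perceive_residue(
            res, merged,
            collinearity_threshold=config.collinearity_threshold,
            planarity_tolerance=config.planarity_tolerance,
        )
        for name, res in retained.items()
    }
    for g in geometries.values():
        warnings.extend(g.warnings)

    gmx = convert_parameters(merged.params, config.pairtypes_mode)
    fixreport = run_fixups(
        retained, geometries, merged.params, config.collinearity_threshold
    )
    problems = check_completeness(retained, geometries, merged.params, fixreport)
    warnings.extend(problems)

    # termini databases, per class and side
    class_of_file = {path: cls for path, _d, cls in config.input_files}
    termini: dict[str, dict[str, list[TerminusEntry]]] = {}
    for side in ("N", "C"):
        same_side = [
            merged.patches[pname]
            for pname, s in config.termini_patches
            if s == side
        ]
        for pname, s in config.termini_patches:
            if s != side:
                continue
            patch = merged.patches[pname]
            patch_file = patch.source.rsplit(":", 1)[0]
            cls = class_of_file.get(patch_file, "prot")
            minted_names = {new for _b, _p, new in config.patched_residues}
            bases = [
                r for r in retained.values()
                if r.chainable and r.group == cls and r.name not in minted_names
            ]
            if not bases:
                warnings.append(f"terminus {pname}: no chainable {cls} residues")
                continue
            entries, w = build_terminus_entry(
                patch, side, bases, same_side,
                config.extra_terminal_deletes, merged,
            )
            warnings.extend(w)
            termini.setdefault(cls, {}).setdefault(side, []).extend(entries)

    # hydrogen addition database
    hdb_rules: dict[str, list[HAddRule]] = {}
    attention: list[AttentionItem] = []
    for name, res in retained.items():
        rule, items = generate_hdb(res, geometries[name], merged)
        hdb_rules.setdefault(res.group or "misc", []).append(rule)
        attention.extend(items)

    layout = None
    if outdir is not None:
        layout = write_port(
            merged, gmx, termini, hdb_rules, fixreport, config, outdir
        )
    return ConversionResult(
        source=merged,
        gmx=gmx,
        geometries=geometries,
        termini=termini,
        hdb_rules=hdb_rules,
        attention=attention,
        fixreport=fixreport,
        layout=layout,
        warnings=warnings,
    )


def run_conversion_from_file(
    config_path: str, outdir: Optional[str] = None
) -> ConversionResult:
    return run_conversion(parse_config(config_path), outdir)
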