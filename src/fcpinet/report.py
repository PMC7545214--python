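"""Full pipeline orchestration and machine-readable run summaries.

``run_pipeline`` chains parse -> membrane frame -> leaflets -> contact
graph -> layers -> coupled pairs -> EET steps -> pathways -> census, writes
TSV/JSON artifacts into the output directory, and returns a summary dict
with a provenance block (input checksum, parameters, tool version).
Summaries carry no timestamps, so identical inputs give byte-identical
JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .census import census
from .exceptions import AnalysisError, ConfigError, FcpinetError, ParseError
from .layers import (
    DEFAULT_CONTACT_CUTOFF,
    assign_layers,
    build_contact_graph,
)
from .membrane import (
    assign_leaflets,
    estimate_frame,
    stromal_reference_from_fes,
)
from .network import (
    DEFAULT_PAIR_CUTOFF,
    DEFAULT_STEP_CUTOFF,
    assemble_pathways,
    derive_eet_steps,
    find_coupled_pairs,
    pathway_report,
    round_half_up,
)
from .structure_io import (
    PigmentClassMap,
    load_chain_config,
    parse_structure,
    pigment_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; cutoffs in Angstrom."""

    input_path: Path
    chain_config_path: Optional[Path] = None
    class_map_path: Optional[Path] = None
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    step_cutoff: float = DEFAULT_STEP_CUTOFF
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF
    stromal_reference: Optional[tuple[float, float, float]] = None
    output_dir: Optional[Path] = None
    strict: bool = False

    def validate(self) -> None:
        for name in ("contact_cutoff", "step_cutoff", "pair_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not Path(self.input_path).exists():
            raise ConfigError(f"input file not found: {self.input_path}")
        if self.chain_config_path is not None \
                and not Path(self.chain_config_path).exists():
            raise ConfigError(f"chain config not found: {self.chain_config_path}")
        if self.class_map_path is not None \
                and not Path(self.class_map_path).exists():
            raise ConfigError(f"class map not found: {self.class_map_path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; return the run summary dict.

    Stage failures propagate with the stage name prefixed; partially
    written artifacts are removed on failure.
    """
    config.validate()
    written: list[Path] = []
    try:
        return _run(config, written)
    except FcpinetError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except FcpinetError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc


def _run(config: RunConfig, written: list[Path]) -> dict:
    class_map = (PigmentClassMap.from_yaml(config.class_map_path, strict=config.strict)
                 if config.class_map_path else PigmentClassMap.default(config.strict))
    chain_cfg = (load_chain_config(config.chain_config_path)
                 if config.chain_config_path else None)

    model = _stage("parse", parse_structure, config.input_path, class_map, chain_cfg)

    ref = config.stromal_reference
    if ref is None:
        ref = stromal_reference_from_fes(model)
    frame = _stage("frame", estimate_frame, model.pigments, ref)
    model = _stage("leaflets", assign_leaflets, model, frame)

    graph = _stage("contacts", build_contact_graph, model, config.contact_cutoff)
    layers = _stage("layers", assign_layers, graph, model.chains)
    pairs = _stage("pairs", find_coupled_pairs, model, config.pair_cutoff)
    steps = _stage("steps", derive_eet_steps, model, layers, config.step_cutoff)
    paths = _stage("pathways", assemble_pathways, steps, model.annotations_by_label)
    census_report = _stage("census", census, model, layers)

    complete = [p for p in paths if p.complete]
    summary = {
        "provenance": {
            "tool": "fcpinet",
            "version": __version__,
            "input": str(config.input_path),
            "input_sha256": _sha256(Path(config.input_path)),
            "parameters": {
                "contact_cutoff": config.contact_cutoff,
                "step_cutoff": config.step_cutoff,
                "pair_cutoff": config.pair_cutoff,
                "stromal_reference": (list(map(float, ref))
                                      if ref is not None else None),
            },
        },
        "membrane_frame": frame.to_dict(),
        "census": census_report.to_dict(),
        "layers": {k: (v if v != float("inf") else "inf")
                   for k, v in sorted(layers.shells.items())},
        "layer_warnings": layers.warnings,
        "n_coupled_pairs": len(pairs),
        "n_steps": len(steps),
        "n_pathways": len(complete),
        "pathway_codes": sorted(p.code for p in complete),
        "incomplete_pathways": sorted(p.code for p in paths if not p.complete),
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)

        def _write(path: Path, writer) -> None:
            written.append(path)
            writer(path)

        _write(out / "pigments.tsv",
               lambda p: pigment_table(model).to_csv(p, sep="\t", index=False))
        _write(out / "layers.tsv",
               lambda p: layers.to_frame(graph).to_csv(p, sep="\t", index=False))
        _write(out / "contacts.json",
               lambda p: p.write_text(json.dumps(graph.to_json_dict(), indent=1)))
        _write(out / "pathways.tsv",
               lambda p: pathway_report(paths).to_csv(p, sep="\t", index=False))
        _write(out / "pairs.tsv", lambda p: _pairs_tsv(pairs, p))
        _write(out / "summary.json",
               lambda p: p.write_text(json.dumps(summary, indent=1, sort_keys=True)))
    return summary


def _pairs_tsv(pairs, path: Path) -> None:
    import pandas as pd

    rows = [{
        "pigment_a": f"{c.pigment_a[0]}:{c.pigment_a[1]}",
        "pigment_b": f"{c.pigment_b[0]}:{c.pigment_b[1]}",
        "subunit_a": c.subunit_a, "subunit_b": c.subunit_b,
        "site_a": c.site_a, "site_b": c.site_b,
        "distance_A": round_half_up(c.distance, 1),
        "leaflet": c.leaflet.value if c.leaflet else "mixed",
        "same_subunit": c.same_subunit,
    } for c in pairs]
    pd.DataFrame(rows, columns=["pigment_a", "pigment_b", "subunit_a", "subunit_b",
                                "site_a", "site_b", "distance_A", "leaflet",
                                "same_subunit"]).to_csv(path, sep="\t", index=False)
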