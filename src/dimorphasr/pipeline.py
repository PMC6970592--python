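"""End-to-end orchestration: volumes -> classification -> per-muscle ASR ->
transition tally -> report bundle.

The pipeline is a pure function of (inputs, config): classification and ML
fitting are deterministic, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .io_data import (HG_MUSCLES, VolumeTable, asr_frame, read_newick,
                      read_volume_table, write_results)
from .mk import (ASRResult, BINARY_STATES, TERNARY_STATES, FitResult,
                 fit_rates, marginal_asr)
from .morphometrics import effect_sizes, effects_frame, normalize, tip_state_map
from .phylo import PhyloTree
from .transitions import (TransitionSummary, count_transitions, state_grid,
                          summarize_across_muscles)

logger = logging.getLogger(__name__)

DEFAULT_STATES_MODE = {"hg1": "binary", "hg2": "ternary",
                       "hg3": "ternary", "hg4": "ternary"}


@dataclass
class PipelineConfig:
    volumes: Union[str, Path, VolumeTable] = ""
    tree: Union[str, Path, PhyloTree] = ""
    outdir: Optional[Union[str, Path]] = None
    threshold: float = 1.5
    min_n: int = 3
    muscles: Sequence[str] = HG_MUSCLES
    states_mode: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STATES_MODE))
    rate_structure: str = "ER"
    root_prior: str = "uniform"
    asr_method: str = "marginal"
    seed: int = 0

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["volumes"] = str(d["volumes"]) if not isinstance(self.volumes, VolumeTable) \
            else getattr(self.volumes, "provenance", "<in-memory>")
        d["tree"] = str(d["tree"]) if not isinstance(self.tree, PhyloTree) \
            else "<in-memory>"
        d["outdir"] = str(d["outdir"]) if d["outdir"] else None
        d["muscles"] = list(self.muscles)
        d["states_mode"] = dict(self.states_mode)
        return d


@dataclass
class MuscleResult:
    muscle: str
    tip_states: dict
    pruned_tree: PhyloTree
    fit: FitResult
    asr: ASRResult
    transitions: TransitionSummary


@dataclass
class PipelineResult:
    effects: pd.DataFrame
    muscles: dict            # muscle -> MuscleResult
    pooled: pd.DataFrame
    grid: pd.DataFrame
    manifest: dict
    paths: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    table = (config.volumes if isinstance(config.volumes, VolumeTable)
             else read_volume_table(config.volumes))
    tree = (config.tree if isinstance(config.tree, PhyloTree)
            else read_newick(config.tree))

    profiles = normalize(table)
    effects = effect_sizes(profiles, muscles=config.muscles,
                           threshold=config.threshold, min_n=config.min_n)
    eff_frame = effects_frame(effects)
    leaf_labels = set(tree.leaf_labels())

    results: dict[str, MuscleResult] = {}
    tip_maps: dict[str, dict] = {}
    summaries: list[TransitionSummary] = []
    for muscle in config.muscles:
        mode = config.states_mode.get(muscle, "ternary")
        tips = tip_state_map(effects, muscle, mode=mode)
        tip_maps[muscle] = tips
        extra = sorted(set(tips) - leaf_labels)
        if extra:
            logger.warning("%s: species absent from tree, dropped: %s",
                           muscle, extra)
            tips = {k: v for k, v in tips.items() if k in leaf_labels}
        if len(tips) < 2:
            raise ValueError(
                f"{muscle}: fewer than 2 species overlap between the tree "
                "and the classified volume table")
        pruned = (tree if set(tips) == leaf_labels
                  else tree.prune_to_taxa(set(tips)))
        states = BINARY_STATES if mode == "binary" else TERNARY_STATES
        fit = fit_rates(pruned, tips, states,
                        rate_structure=config.rate_structure,
                        root_prior=config.root_prior)
        asr = marginal_asr(pruned, tips, fit.model, method=config.asr_method)
        summary = count_transitions(asr, tips, pruned, muscle=muscle)
        summaries.append(summary)
        results[muscle] = MuscleResult(muscle=muscle, tip_states=tips,
                                       pruned_tree=pruned, fit=fit,
                                       asr=asr, transitions=summary)
        logger.info("%s: %d taxa, q_hat=%s, logL=%.4f, %d transition(s)",
                    muscle, len(tips), fit.model.rates, fit.log_likelihood,
                    summary.grand_total)

    pooled = summarize_across_muscles(summaries)
    grid = state_grid(tip_maps)
    manifest = {
        "tool": "dimorphasr", "version": __version__,
        "config": config.to_manifest(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_manifest(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_records": len(table.records),
        "n_complete": len(table.complete_records()),
        "per_muscle": {
            m: {"n_taxa": len(r.tip_states),
                "rates": list(r.fit.model.rates),
                "log_likelihood": r.fit.log_likelihood,
                "at_lower_bound": r.fit.at_lower_bound,
                "n_transitions": r.transitions.grand_total,
                "parsimony_score": r.transitions.parsimony_score}
            for m, r in results.items()},
    }

    out = PipelineResult(effects=eff_frame, muscles=results, pooled=pooled,
                         grid=grid, manifest=manifest)
    if config.outdir:
        out.paths = write_results(
            config.outdir, effects_frame=eff_frame,
            asr_frames={m: asr_frame(r.pruned_tree, r.asr)
                        for m, r in results.items()},
            manifest=manifest)
        outdir = Path(config.outdir)
        p = outdir / "transitions.tsv"
        pooled.to_csv(p, sep="\t", index=False)
        out.paths["transitions"] = p
        p = outdir / "state_grid.tsv"
        grid.to_csv(p, sep="\t", index=False)
        out.paths["state_grid"] = p
    return out
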