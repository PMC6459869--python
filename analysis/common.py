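"""Shared study configuration for the numbered analysis scripts.

One simulated ChIP-Rx experiment with three conditions sharing a genome
layout:

* ``WT`` — spreading H3K27me3 (decay length 1200 bp, full global level);
* ``Ezh2KO`` — confined deposition (decay 0) at 30% global level, the
  EZH1-only regime where the mark stays within the PRC2 footprint;
* ``dKO`` — near-complete loss (2% residual), the no-PRC2-activity control.

The experiment is regenerated deterministically by every script (seed 1337),
so the drivers need no intermediate files.
"""
from pathlib import Path

from polyspread import SimulationConfig, simulate_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1337

BASE = dict(seed=SEED, ip_depth=2_000_000, input_depth=500_000)

CONDITIONS = {
    "WT": dict(decay_length=1200.0, global_level=1.0),
    "Ezh2KO": dict(decay_length=0.0, global_level=0.3),
    "dKO": dict(decay_length=0.0, global_level=0.02),
}


def build_experiment(include_h3k36me3: bool = True):
    configs = {
        name: SimulationConfig(**BASE, **params)
        for name, params in CONDITIONS.items()
    }
    return simulate_experiment(configs, include_h3k36me3=include_h3k36me3)


def outdir(stage: str) -> Path:
    d = RESULTS / stage
    d.mkdir(parents=True, exist_ok=True)
    return d
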