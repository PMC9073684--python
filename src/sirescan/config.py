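"""YAML config support for the command-line interface.

A config file may override the codon-set list, the frequency-bin edges
and scan flags, e.g.::

    min_instances: 10
    multiallelic: rarest
    tail_bins: 3
    frame_offset: 0
    bin_edges: [0.0, 0.015625, 0.03125, 0.0625, 0.125, 0.25, 0.5]
    codon_sets:
      - name: Phe/Leu
        kind: same_mutation_quartet
        codons: [TTT, TTC, CTT, CTC]
        syn_positions: [3]
        nonsyn_positions: [1]

Command-line flags take precedence over config values.
"""

from __future__ import annotations

import yaml

from .codon_sets import CodonSet, builtin_codon_sets, sets_from_config
from .spectrum import FrequencyBin, bins_from_edges, default_bins

__all__ = ["load_config", "sets_from", "bins_from"]

_KNOWN_KEYS = {"min_instances", "multiallelic", "tail_bins", "frame_offset",
               "bin_edges", "codon_sets", "indel_mode"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def sets_from(cfg: dict) -> list[CodonSet]:
    if "codon_sets" in cfg:
        return sets_from_config(cfg["codon_sets"])
    return builtin_codon_sets()


def bins_from(cfg: dict) -> list[FrequencyBin]:
    if "bin_edges" in cfg:
        return bins_from_edges([float(e) for e in cfg["bin_edges"]])
    return default_bins()
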