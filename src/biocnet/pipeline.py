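"""End-to-end pipeline: corpus -> network -> core -> tables -> files.

Everything the command line writes is produced here so the run is testable
without a shell.  Outputs are deterministic: re-running on identical inputs
and configuration yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from .core import average_path_length, direct_biophysical_support, ego_network, ego_table, extract_core
from .corpus import Corpus
from .errors import FormatError
from .network import build_network, connectivity_summary, standardize_weights, value_frequencies


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis choices, defaulting to the study conventions: divide-by-max
    standardization, 5% core with boundary ties included, directed paths and
    ego counts that include the ego node."""

    standardization: str = "divide_by_max"
    core_fraction: float = 0.05
    tie_policy: str = "include_ties"
    path_direction: str = "directed"
    include_ego: bool = True
    frequency_unit: str = "segment"

    def __post_init__(self) -> None:
        if not 0.0 < self.core_fraction <= 1.0:
            raise FormatError("core_fraction must be in (0, 1]")
        allowed = {
            "standardization": ("divide_by_max", "min_max"),
            "tie_policy": ("include_ties", "strict_count"),
            "path_direction": ("directed", "undirected"),
            "frequency_unit": ("segment", "mention"),
        }
        for name, tokens in allowed.items():
            if getattr(self, name) not in tokens:
                raise FormatError(
                    f"{name} must be one of {tokens}, got {getattr(self, name)!r}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    corpus: Corpus,
    outdir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    input_paths: dict[str, str | Path] | None = None,
) -> dict:
    """Run the full analysis and write the standard output tree.

    Writes network/core GraphML, frequency, connectivity, support and ego
    tables, one ego GraphML per core biophysical node, ``metrics.json`` and
    a ``manifest.json`` recording configuration and input checksums.
    Returns the metrics dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    network = standardize_weights(
        build_network(corpus), mode=config.standardization
    )
    core = extract_core(
        network, fraction=config.core_fraction, tie_policy=config.tie_policy
    )

    network.to_graphml(outdir / "network.graphml")
    network.write_edge_list(outdir / "network_edges.csv")
    core.network.to_graphml(outdir / "core.graphml")

    value_frequencies(corpus, unit=config.frequency_unit).to_csv(
        outdir / "frequencies.csv", index=False, float_format="%.10g"
    )
    connectivity = connectivity_summary(network)
    connectivity["per_node"].to_csv(outdir / "connectivity.csv", index=False)
    direct_biophysical_support(core).to_csv(
        outdir / "support_table.csv", index=False
    )
    ego_summary = ego_table(core, include_ego=config.include_ego)
    ego_summary.to_csv(outdir / "ego_table.csv", index=False)

    for element in core.network.biophysical_nodes:
        for k in (1, 2):
            ego = ego_network(core, element, k=k)
            nx.write_graphml(
                ego.graph, str(outdir / f"ego_{element.lower()}_k{k}.graphml")
            )

    paths = average_path_length(core, direction=config.path_direction)
    metrics = {
        "n_segments": len(corpus),
        "n_mentions": corpus.n_mentions,
        "n_nodes": network.graph.number_of_nodes(),
        "n_edges": network.n_edges,
        "max_raw_weight": int(network.provenance["max_raw_weight"]),
        "core": core.summary(),
        "avg_path_length": paths.mean,
        "n_unreachable_pairs": paths.n_unreachable_pairs,
        "connectivity": connectivity["aggregates"],
    }
    (outdir / "metrics.json").write_text(
        json.dumps(metrics, indent=1, sort_keys=True) + "\n"
    )

    manifest = {
        "biocnet_version": __version__,
        "config": asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (input_paths or {}).items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return metrics
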