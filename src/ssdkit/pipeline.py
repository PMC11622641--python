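"""End-to-end orchestration: specificity -> SP -> SDP -> volcano -> networks.

One seed in the config governs every stochastic stage (permutations, splits)
through per-stage substreams, so a rerun with the same config produces
byte-identical outputs.  Every TSV carries a provenance comment line with
the package version, seed and stage parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .diversity import DEFAULT_ORDERS
from .landscape import OTUTable, build_landscape, load_metadata, load_otu_table
from .networks import (
    build_specificity_matrix,
    correlation_network,
    core_periphery,
    detect_clusters,
    write_edge_list,
    write_graphml,
    write_summary,
)
from .permutation import (
    assemblages_from_classifications,
    sdp_frame,
    sdp_test,
    sp_frame,
    sp_test,
)
from .specificity import species_specificity, write_specificity_table
from .volcano import category_counts, volcano_frame, volcano_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full"]


@dataclass
class PipelineConfig:
    otu_path: str
    meta_path: str
    habitats: tuple[str, str]
    sites: list[str] = field(default_factory=list)  # empty = all sites in metadata
    n_perm: int = 1000
    alpha: float = 0.05
    alpha_network: float = 0.01
    orders: tuple[float, ...] = DEFAULT_ORDERS
    seed: int = 0
    out_dir: str = "ssd_output"

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.alpha_network < 1:
            raise ValueError("alpha values must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _provenance(config: PipelineConfig, stage: str, site: str | None = None) -> str:
    bits = [
        f"ssdkit {__version__}",
        f"stage={stage}",
        f"seed={config.seed}",
        f"n_perm={config.n_perm}",
        f"alpha={config.alpha}",
    ]
    if site is not None:
        bits.append(f"site={site}")
    return " | ".join(bits)


def run_full(config: PipelineConfig) -> Path:
    """Run the whole framework and write per-site and per-cohort artifacts.

    Per site: specificity list, SP classification, SDP table, volcano table;
    across sites: a category-count summary and (with >= 3 sites) SSN/SHN
    exports per cohort.  A manifest records parameters and completion; on a
    stage failure partial outputs are kept and the manifest marks the stage
    that failed before the error propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_otu_table(config.otu_path)
    meta = load_metadata(config.meta_path)
    sites = config.sites or sorted(meta["site"].unique())
    ha, hb = config.habitats
    rng = np.random.default_rng(config.seed)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "alpha_network": config.alpha_network,
        "orders": list(config.orders),
        "habitats": [ha, hb],
        "sites": sites,
        "complete": False,
        "failed_stage": None,
        "outputs": [],
    }

    def emit(path: Path) -> None:
        manifest["outputs"].append(path.name)

    per_site = {}
    stage = "init"
    try:
        for site in sites:
            sp_seed, sdp_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
            stage = f"specificity[{site}]"
            landscape = build_landscape(table, meta, site, (ha, hb))
            spec = species_specificity(landscape)
            path = out / f"specificity_{site}.tsv"
            write_specificity_table(spec, path, _provenance(config, stage, site))
            emit(path)

            stage = f"sp_test[{site}]"
            cls = sp_test(
                landscape, n_perm=config.n_perm, alpha=config.alpha, seed=sp_seed
            )
            per_site[site] = cls
            path = out / f"sp_{site}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(f"# {_provenance(config, stage, site)}\n")
                sp_frame(cls).to_csv(fh, sep="\t")
            emit(path)

            stage = f"sdp_test[{site}]"
            sdp = sdp_test(
                landscape,
                assemblages_from_classifications(cls),
                orders=config.orders,
                n_perm=config.n_perm,
                seed=sdp_seed,
            )
            path = out / f"sdp_{site}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(f"# {_provenance(config, stage, site)}\n")
                sdp_frame(sdp).to_csv(fh, sep="\t", index=False)
            emit(path)

            stage = f"volcano[{site}]"
            points = volcano_table(cls)
            path = out / f"volcano_{site}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(f"# {_provenance(config, stage, site)}\n")
                volcano_frame(points).to_csv(fh, sep="\t")
            emit(path)

        stage = "category_counts"
        path = out / "category_counts.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {_provenance(config, stage)}\n")
            category_counts(per_site).to_csv(fh, sep="\t")
        emit(path)

        if len(sites) >= 3:
            for cohort in (ha, hb):
                stage = f"network[{cohort}]"
                matrix = build_specificity_matrix(table, meta, cohort, sites)
                for mode in ("SSN", "SHN"):
                    net = correlation_network(
                        matrix, mode=mode, alpha=config.alpha_network
                    )
                    core_periphery(net, seed=config.seed)
                    if net.graph.number_of_edges() > 0:
                        detect_clusters(net, seed=config.seed)
                    base = out / f"{mode.lower()}_{cohort}"
                    write_edge_list(
                        net,
                        base.with_suffix(".edges.tsv"),
                        _provenance(config, stage),
                    )
                    write_graphml(net, base.with_suffix(".graphml"))
                    write_summary(net, base.with_suffix(".json"))
                    for suffix in (".edges.tsv", ".graphml", ".json"):
                        emit(base.with_suffix(suffix))
        manifest["complete"] = True
    except Exception:
        manifest["failed_stage"] = stage
        raise
    finally:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
    logger.info("pipeline complete: %d artifacts in %s", len(manifest["outputs"]), out)
    return out
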