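"""End-to-end orchestration: simulate, mine, catalogue, quantify, compare.

A single declarative ``RunConfig`` (YAML-loadable) drives the whole
pipeline; all randomness flows from one master seed, and a manifest with
the seed and a config hash is written so a run can be reproduced
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bchrom import compare_abundances, targeted_recluster
from .catalog import catalog_fasta_records, catalog_table, group, name_families
from .cytostats import summarize_rul, symmetry_index
from .datasets import a_pattern_records, load_b_locations
from .discovery import MineConfig, mine_satellitome
from .errors import InvalidParameterError
from .quantify import quantify_library
from .simgen import FamilySpec, plant_families, simulate_reads, write_fasta

log = logging.getLogger("satellitome")


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "satellitome_run"
    prefix: str = "Syn"
    # genome
    background_length: int = 50_000
    b_fraction: float = 0.08
    families: list = field(default_factory=list)  # list of FamilySpec kwargs
    # reads
    n_pairs: int = 100_000
    read_len: int = 101
    insert_mean: int = 300
    error_rate: float = 0.002
    diploid_equivalent: bool = True
    # mining
    start_pairs: int = 1_000
    max_iterations: int = 8
    # thresholds
    variant_identity: float = 95.0
    family_identity: float = 80.0
    superfamily_identity: float = 50.0
    mask_min_identity: float = 0.70
    mask_min_len: int = 30
    mask_pairs_cap: int = 10_000_000
    recluster_pairs: int = 2500

    def __post_init__(self) -> None:
        for name in ("variant_identity", "family_identity", "superfamily_identity"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise InvalidParameterError(f"{name}={v} outside (0, 100]")
        if not 0 < self.mask_min_identity <= 1:
            raise InvalidParameterError("mask_min_identity outside (0, 1]")
        if self.start_pairs < 1_000:
            raise InvalidParameterError("start_pairs must be >= 1,000")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def family_specs(self) -> list[FamilySpec]:
        if self.families:
            return [FamilySpec(**kw) for kw in self.families]
        return demo_family_specs()


def demo_family_specs() -> list[FamilySpec]:
    """Default demo satellitome: three shared families plus one B-restricted."""
    return [
        FamilySpec(label="famA", rul=51, copies_0b=40, copies_b=3, intra_divergence=0.02),
        FamilySpec(label="famB", rul=23, copies_0b=60, copies_b=5, intra_divergence=0.03),
        FamilySpec(label="famC", rul=91, copies_0b=12, copies_b=1, intra_divergence=0.02),
        FamilySpec(
            label="famB-restricted",
            rul=40,
            copies_b=60,
            b_restricted=True,
            dispersed_copies_0b=4,
            intra_divergence=0.02,
        ),
    ]


def run(config: RunConfig) -> dict:
    """Execute every stage and write the run outputs.

    Returns a dict with the in-memory products (genomes, catalogue,
    abundance tables, comparison table, cytogenetic summaries).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(name)s %(message)s")
    stages: list[dict] = []
    t_all = time.time()
    master = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(6)]

    def stage(name):
        log.info("stage %s", name)
        stages.append({"stage": name, "t": round(time.time() - t_all, 2)})

    try:
        stage("simgen")
        specs = config.family_specs()
        pair = plant_families(specs, config.background_length, config.b_fraction, seed=seeds[0])
        write_fasta(out / "genome_0B.fasta", [("genome_0B", pair.seq_0b)])
        write_fasta(out / "genome_1B.fasta", [("genome_1B", pair.seq_1b)])
        pair.truth.to_tsv(out / "truth.tsv")
        libs = {}
        for i, genome in enumerate(("0B", "1B")):
            template = pair.simulation_template(genome, config.diploid_equivalent)
            libs[genome] = simulate_reads(
                template,
                n_pairs=config.n_pairs,
                read_len=config.read_len,
                insert_mean=config.insert_mean,
                error_rate=config.error_rate,
                seed=seeds[1] + i,
                label=genome,
            )

        stage("mine")
        # mine the two libraries combined, half of each
        from .simgen import ReadLibrary

        combined = ReadLibrary(
            r1=np.concatenate([libs["0B"].r1[: config.n_pairs // 2], libs["1B"].r1[: config.n_pairs // 2]]),
            r2=np.concatenate([libs["0B"].r2[: config.n_pairs // 2], libs["1B"].r2[: config.n_pairs // 2]]),
            read_len=config.read_len,
            error_rate=config.error_rate,
            seed=seeds[2],
            label="combined",
        )
        mine_cfg = MineConfig(
            start_pairs=config.start_pairs,
            max_iterations=config.max_iterations,
            dedup_identity=config.family_identity,
            seed=seeds[2],
        )
        mining = mine_satellitome(combined, mine_cfg)
        mining.to_frame().to_csv(out / "mining_log.tsv", sep="\t", index=False)
        write_fasta(
            out / "mined_monomers.fasta",
            [
                (f"iter{m.iteration}_cluster{m.cluster_index}_len{m.period}", m.consensus)
                for m in mining.monomers
            ],
        )

        stage("catalog")
        families, superfamilies = group(
            mining.monomers,
            variant_threshold=config.variant_identity,
            family_threshold=config.family_identity,
            superfamily_threshold=config.superfamily_identity,
        )

        stage("quantify")
        tables = {}
        named = None
        comparison = None
        if families:
            # before naming, families are keyed by consensus sequence
            table0 = quantify_library(
                libs["0B"],
                families,
                genome="0B",
                max_pairs=config.mask_pairs_cap,
                min_identity=config.mask_min_identity,
                min_len=config.mask_min_len,
                seed=seeds[3],
            )
            abundance0 = dict(zip(table0["family"], table0["abundance_percent"]))
            named = name_families(families, abundance0, prefix=config.prefix)
            catalogue_rows = catalog_table(named)
            for genome in ("0B", "1B"):
                tables[genome] = quantify_library(
                    libs[genome],
                    named,
                    genome=genome,
                    max_pairs=config.mask_pairs_cap,
                    min_identity=config.mask_min_identity,
                    min_len=config.mask_min_len,
                    seed=seeds[3],
                )
                tables[genome].to_csv(out / f"abundance_{genome}.tsv", sep="\t", index=False)
            write_fasta(out / "catalog.fasta", catalog_fasta_records(named))
            satellitome_tsv = catalogue_rows.merge(
                tables["0B"][["family", "abundance_percent", "divergence_percent"]].rename(
                    columns={"abundance_percent": "abundance_0b", "divergence_percent": "divergence_0b"}
                ),
                left_on="name",
                right_on="family",
            ).merge(
                tables["1B"][["family", "abundance_percent", "divergence_percent"]].rename(
                    columns={"abundance_percent": "abundance_1b", "divergence_percent": "divergence_1b"}
                ),
                left_on="name",
                right_on="family",
            )[
                ["name", "rul", "at_percent", "v", "superfamily", "divergence_0b", "divergence_1b", "abundance_0b", "abundance_1b"]
            ]

            stage("bchrom")
            comparison = compare_abundances(tables["0B"], tables["1B"], f=config.b_fraction)
            satellitome_tsv = satellitome_tsv.merge(
                comparison[["family", "log2_ratio", "classification"]],
                left_on="name",
                right_on="family",
            ).drop(columns=["family"])
            satellitome_tsv.to_csv(out / "satellitome.tsv", sep="\t", index=False)
            comparison.to_csv(out / "b_comparison.tsv", sep="\t", index=False)
            # verify candidate B-specific families by targeted reclustering
            reports = []
            for _, row in comparison.iterrows():
                if row["classification"] in ("B-enriched candidate", "undefined") and row["a1"] > 0:
                    fam = next(f for f in named if f.name == row["family"])
                    rep = targeted_recluster(
                        libs["0B"], libs["1B"], fam.consensus, n=config.recluster_pairs
                    )
                    reports.append(
                        {
                            "family": row["family"],
                            "tandem_in_0B": rep["0B"].tandem_detected,
                            "tandem_in_1B": rep["1B"].tandem_detected,
                            "pairs_0B": rep["0B"].n_selected_pairs,
                            "pairs_1B": rep["1B"].n_selected_pairs,
                        }
                    )
            pd.DataFrame(reports).to_csv(out / "b_specificity.tsv", sep="\t", index=False)

        stage("cytostats")
        catalog_df = load_reference_summaries(out)

        stage("manifest")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "stages": stages,
            "n_families_mined": len(families),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:  # partial outputs are preserved in out_dir
        failed = stages[-1]["stage"] if stages else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    return {
        "genomes": pair,
        "libraries": libs,
        "mining": mining,
        "families": named if named is not None else families,
        "superfamilies": superfamilies,
        "abundance": tables,
        "comparison": comparison,
        "cytostats": catalog_df,
    }


def load_reference_summaries(out_dir: Optional[Path] = None) -> dict:
    """Cytogenetic statistics of the packaged reference tables."""
    from .datasets import load_satellitome_catalog

    catalog_df = load_satellitome_catalog()
    rul_summary = summarize_rul(catalog_df, a_pattern_records("A. paranae"))
    b_records = load_b_locations()
    si = {}
    for b_name in sorted({r.chromosome for r in b_records}):
        si[b_name] = symmetry_index([r for r in b_records if r.chromosome == b_name])
    summary = {
        "rul": rul_summary,
        "symmetry": {k: dataclasses.asdict(v) for k, v in si.items()},
    }
    if out_dir is not None:
        from .cytostats import format_report, statistics_report
        from .datasets import load_a_patterns

        (Path(out_dir) / "cytostats_summary.json").write_text(json.dumps(summary, indent=2))
        report = statistics_report(
            catalog_df, a_pattern_records("A. paranae"), b_records, load_a_patterns()
        )
        report.to_csv(Path(out_dir) / "cytostats_report.tsv", sep="\t", index=False)
        (Path(out_dir) / "cytostats_report.txt").write_text(format_report(report))
    return summary
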