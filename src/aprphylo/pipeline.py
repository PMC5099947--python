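"""End-to-end pipeline orchestration and the run manifest.

Stage order: reference curation -> reference tree with dual supports ->
primer coverage / amplicon extraction -> clone translation and mapping ->
OTU clustering -> parsimony placement of OTU representatives ->
group assignment, count table and concordance with a de-novo partial tree.

Every stage writes plain-text outputs (TSV, FASTA, Newick) into the run
directory; a machine-readable ``manifest.json`` records package and library
versions, all seeds and parameters, and sha256 checksums of inputs and
outputs, so a run can be reproduced byte-identically. Every excluded
sequence is logged with a reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import classify as classify_mod
from . import otu as otu_mod
from . import phylo, placement, primer as primer_mod, refset

log = logging.getLogger("aprphylo")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    reference_fasta_b: str
    reference_fasta_a: str
    reference_metadata: str
    library_manifest: str
    group_map: str
    output_dir: str
    thresholds: tuple[int, int, int] = refset.DEFAULT_THRESHOLDS
    tree_model: str = "poisson"
    tree_overlay_model: str = "p"
    bootstrap_reps: int = 100
    tree_seed: int = 0
    placement_mode: str = "independent"
    min_overlap: int = 50
    otu_cutoff: float = 0.02
    otu_linkage: str = "average"
    otu_seed: int = 0
    primer_forward: dict | None = None
    primer_reverse: dict | None = None
    primer_max_mismatch: int = 3
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        def resolve(p: str) -> str:
            path = Path(p)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            return str(path)

        try:
            ref = raw["reference"]
            cfg = cls(
                reference_fasta_b=resolve(ref["fasta_b"]),
                reference_fasta_a=resolve(ref["fasta_a"]),
                reference_metadata=resolve(ref["metadata"]),
                library_manifest=resolve(raw["libraries"]["manifest"]),
                group_map=resolve(raw["groups"]["map"]),
                output_dir=resolve(raw["output_dir"]),
                raw=raw,
            )
        except KeyError as exc:
            raise ValueError(f"config missing required key: {exc}") from None
        if "thresholds" in ref:
            cfg.thresholds = tuple(ref["thresholds"])
        tree = raw.get("tree", {})
        cfg.tree_model = tree.get("model", cfg.tree_model)
        cfg.tree_overlay_model = tree.get("overlay_model", cfg.tree_overlay_model)
        cfg.bootstrap_reps = int(tree.get("bootstrap_reps", cfg.bootstrap_reps))
        cfg.tree_seed = int(tree.get("seed", cfg.tree_seed))
        pl = raw.get("placement", {})
        cfg.placement_mode = pl.get("mode", cfg.placement_mode)
        cfg.min_overlap = int(pl.get("min_overlap", cfg.min_overlap))
        ot = raw.get("otu", {})
        cfg.otu_cutoff = float(ot.get("cutoff", cfg.otu_cutoff))
        cfg.otu_linkage = ot.get("linkage", cfg.otu_linkage)
        cfg.otu_seed = int(ot.get("seed", cfg.otu_seed))
        pr = raw.get("primers")
        if pr:
            cfg.primer_forward = dict(pr["forward"])
            cfg.primer_reverse = dict(pr["reverse"])
            cfg.primer_max_mismatch = int(pr.get("max_mismatch", cfg.primer_max_mismatch))
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns a summary dict (also written as manifest)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    exclusions: list[dict] = []
    summary: dict[str, Any] = {}
    try:
        # ---- stage: build-ref -------------------------------------------
        stage = "build-ref"
        try:
            records = refset.read_sequence_set(
                {"B": config.reference_fasta_b, "A": config.reference_fasta_a},
                config.reference_metadata,
            )
            partition = refset.partition_sequence_set(records, config.thresholds)
            partition.table(records).to_csv(out / "partition.tsv", sep="\t", index=False)
            core_records = [r for r in records if r.record_id in partition.core]
            if len(core_records) < 4:
                raise ValueError(f"only {len(core_records)} core records; need >= 4")
            align_b = refset.alignment_from_records(core_records, "B")
            align_a = refset.alignment_from_records(core_records, "A")
            concat = refset.concatenate_subunits(align_b, align_a)
            masked = refset.mask_incomplete_columns(concat)
            refset.write_masked_fasta(masked, out / "reference_masked.fasta")
            for rid in partition.rejected:
                exclusions.append({"stage": stage, "id": rid, "reason": "below length thresholds"})
            widths = refset.masked_widths(masked)
            summary["reference"] = {
                "n_core": len(partition.core),
                "n_shorter": len(partition.shorter),
                "n_rejected": len(partition.rejected),
                "masked_columns_B": widths[0],
                "masked_columns_A": widths[1],
            }
            log.info("build-ref: %s", summary["reference"])
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: tree -------------------------------------------------
        stage = "tree"
        try:
            dm = phylo.distance_matrix(masked, config.tree_model, "complete")
            dm.write_tsv(out / "reference_distances.tsv")
            primary = phylo.bootstrap_supports(
                masked, config.tree_model, config.bootstrap_reps, config.tree_seed
            )
            secondary = phylo.bootstrap_supports(
                masked,
                config.tree_overlay_model,
                config.bootstrap_reps,
                config.tree_seed + 1,
            )
            consensus = phylo.overlay_supports(primary.tree, secondary.supports)
            consensus.write(out / "consensus_tree.nwk", supports=True)
            summary["tree"] = {
                "n_leaves": consensus.n_leaves,
                "bootstrap_reps": config.bootstrap_reps,
                "skipped_replicates": primary.n_skipped + secondary.n_skipped,
            }
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: libraries / primer / otu ----------------------------
        stage = "otu"
        try:
            manifest = pd.read_csv(config.library_manifest, sep="\t", dtype=str).fillna("")
            base = Path(config.library_manifest).parent
            libraries = []
            for _, row in manifest.iterrows():
                fasta = Path(row["fasta_path"])
                if not fasta.is_absolute():
                    fasta = base / fasta
                libraries.append(
                    otu_mod.CloneLibrary.from_fasta(
                        row["library_name"], fasta,
                        site=row.get("site", ""), depth=row.get("depth", ""),
                        date=row.get("date", ""),
                    )
                )
            clone_library_of = {
                cid: lib.library_name for lib in libraries for cid, _ in lib.clones
            }
            fw = rv = None
            if config.primer_forward and config.primer_reverse:
                fw = primer_mod.PrimerSpec(
                    config.primer_forward["name"],
                    config.primer_forward["seq"],
                    config.primer_forward.get("orientation", "forward"),
                )
                rv = primer_mod.PrimerSpec(
                    config.primer_reverse["name"],
                    config.primer_reverse["seq"],
                    config.primer_reverse.get("orientation", "reverse"),
                )
                all_nt = {cid: nt for lib in libraries for cid, nt in lib.clones}
                cov = primer_mod.coverage_table((fw, rv), all_nt)
                cov.to_csv(out / "primer_coverage.tsv", sep="\t", index=False)
                primer_mod.coverage_histogram(cov).to_csv(
                    out / "primer_coverage_histogram.tsv", sep="\t", index=False
                )

            proteins: dict[str, str] = {}
            for lib in libraries:
                for cid, nt in lib.clones:
                    template = nt
                    if fw and rv:
                        amp = primer_mod.extract_amplicon_region(
                            fw, rv, nt, config.primer_max_mismatch
                        )
                        if not amp.amplified:
                            exclusions.append(
                                {"stage": stage, "id": cid,
                                 "reason": f"no amplicon: {amp.reason}"}
                            )
                            continue
                        template = amp.amplicon
                    aa, frame = otu_mod.translate_best_frame(template, "auto")
                    if "*" in aa[:-1]:
                        exclusions.append(
                            {"stage": stage, "id": cid,
                             "reason": f"internal stop in best frame {frame}"}
                        )
                        continue
                    proteins[cid] = aa

            mapped: dict[str, placement.QueryAlignment] = {}
            for cid, aa in proteins.items():
                try:
                    mapped[cid] = placement.align_query_to_reference(
                        aa, masked, query_id=cid, min_overlap=config.min_overlap
                    )
                except ValueError as exc:
                    exclusions.append({"stage": stage, "id": cid, "reason": str(exc)})
            if len(mapped) < 2:
                raise ValueError("fewer than 2 clones survive mapping")
            mask_cols = masked.mask_order
            mapped_rows = {
                cid: "".join(q.residues[c] for c in mask_cols)
                for cid, q in mapped.items()
            }
            clone_dm = phylo.distance_matrix(mapped_rows, "poisson", "pairwise")
            otus = otu_mod.cluster_otus(clone_dm, config.otu_cutoff, config.otu_linkage)
            otus = otu_mod.pick_representatives(otus, config.otu_seed)
            otus.table().to_csv(out / "otus.tsv", sep="\t", index=False)
            otus.write_list_format(out / "otus.list")
            summary["otu"] = {
                "n_clones_in": sum(len(lib.clones) for lib in libraries),
                "n_clones_clustered": len(mapped),
                "n_otus": otus.n_otus,
                "cutoff": config.otu_cutoff,
                "linkage": config.otu_linkage,
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: placement -------------------------------------------
        stage = "place"
        try:
            rep_queries = [mapped[rep] for rep in otus.representatives.values()]
            results, extended, failures = placement.place_batch(
                consensus, masked, rep_queries, mode=config.placement_mode
            )
            for qid, reason in failures:
                exclusions.append({"stage": stage, "id": qid, "reason": reason})
            extended.write(out / "extended_tree.nwk")
            placements_df = pd.DataFrame(
                [
                    {
                        "query_id": r.query_id,
                        "edge": "|".join(sorted(r.best_edge)),
                        "delta": r.delta_score,
                        "n_ties": len(r.tie_edges),
                        "covered_columns": r.covered_columns_count,
                    }
                    for r in results
                ]
            )
            summary["placement"] = {
                "n_placed": len(results),
                "n_failed": len(failures),
                "mode": config.placement_mode,
            }
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: classify --------------------------------------------
        stage = "classify"
        try:
            gmap = pd.read_csv(config.group_map, sep="\t", dtype=str).fillna("")
            leaf_to_group = dict(zip(gmap["record_id"], gmap["group_name"]))
            leaf_to_group = {
                k: v for k, v in leaf_to_group.items() if k in set(consensus.leaf_names)
            }
            roles = None
            if "role" in gmap.columns:
                roles = dict(zip(gmap["group_name"], gmap["role"]))
            groups = classify_mod.define_groups(consensus, leaf_to_group, roles)
            rep_to_otu = {rep: otu_id for otu_id, rep in otus.representatives.items()}
            assignments = {
                rep_to_otu[r.query_id]: classify_mod.assign_group(r, groups)
                for r in results
            }
            placements_df["group"] = [
                assignments[rep_to_otu[r.query_id]] for r in results
            ]
            placements_df.to_csv(out / "placements.tsv", sep="\t", index=False)
            counts = classify_mod.group_count_table(
                assignments, otus, clone_library_of, groups
            )
            counts.to_csv(out / "group_counts.tsv", sep="\t", index_label="group")

            # de-novo comparison tree over the partial (mapped) region only
            ref_rows = masked.masked_rows()
            combined = dict(ref_rows)
            rep_ids = [r.query_id for r in results]
            combined.update({rid: mapped_rows[rid] for rid in rep_ids})
            denovo_dm = phylo.distance_matrix(combined, "poisson", "pairwise")
            denovo_tree = phylo.neighbor_joining(denovo_dm)
            denovo_tree.write(out / "denovo_partial_tree.nwk")
            # group definitions stay those of the reference tree; the
            # de-novo tree only supplies each query's neighborhood
            ref_leaves = frozenset(ref_rows)
            denovo_assignments = {
                rep_to_otu[rid]: classify_mod.assign_by_membership(
                    denovo_tree, rid, groups, ref_leaves
                )
                for rid in rep_ids
            }
            fraction, diffs = classify_mod.classification_concordance(
                assignments, denovo_assignments
            )
            diffs.to_csv(out / "concordance_diffs.tsv", sep="\t", index=False)
            summary["classify"] = {
                "n_groups": len(groups),
                "n_unclassified": sum(1 for g in assignments.values() if g == "unclassified"),
                "concordance_consensus_vs_partial": round(fraction, 4),
            }
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- manifest ----------------------------------------------------
        pd.DataFrame(exclusions, columns=["stage", "id", "reason"]).to_csv(
            out / "exclusions.tsv", sep="\t", index=False
        )
        for exc_row in exclusions:
            log.info("excluded [%s] %s: %s", exc_row["stage"], exc_row["id"], exc_row["reason"])
        inputs = {
            name: _sha256(Path(p))
            for name, p in {
                "reference_fasta_b": config.reference_fasta_b,
                "reference_fasta_a": config.reference_fasta_a,
                "reference_metadata": config.reference_metadata,
                "library_manifest": config.library_manifest,
                "group_map": config.group_map,
            }.items()
        }
        outputs = {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.suffix in (".tsv", ".nwk", ".fasta", ".list")
        }
        params = {
            k: v for k, v in asdict(config).items() if k != "raw"
        }
        manifest_doc = {
            "aprphylo_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "parameters": params,
            "seeds": {
                "tree": config.tree_seed,
                "tree_overlay": config.tree_seed + 1,
                "otu_representatives": config.otu_seed,
            },
            "input_checksums": inputs,
            "output_checksums": outputs,
            "summary": summary,
        }
        (out / "manifest.json").write_text(json.dumps(manifest_doc, indent=2, default=str) + "\n")
        return manifest_doc
    finally:
        log.removeHandler(handler)
        handler.close()
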