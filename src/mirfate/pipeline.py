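"""Staged analysis pipeline: simulate -> quantify -> arm-prefs -> switch ->
conserve -> copies -> synteny -> report.

Every stage reads and writes plain files under one output directory, so
stages are individually invokable and resumable: a stage is skipped when
its recorded input/parameter checksum is unchanged and its outputs exist.
Tables are TSV with a single '#'-prefixed header line; nested summaries are
JSON with sorted keys and no timestamps, so identical configurations and
seeds reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from mirfate import catalog as cat
from mirfate import fates, preference, quantify, simulate, synteny

log = logging.getLogger("mirfate")

STAGES = (
    "simulate",
    "quantify",
    "arm_prefs",
    "switch",
    "conserve",
    "copies",
    "synteny",
    "report",
)

DEFAULT_CONFIG: dict = {
    "simulation": None,  # dict of SimConfig overrides, or None for external inputs
    "inputs": None,  # external input paths when simulation is None
    "quantify": {
        "policy": "fractional",
        "max_mismatches": 1,
        "min_mean_phred": 20.0,
        "min_len": 18,
        "max_len": 27,
    },
    "preference": {
        "aur_high": 0.7,
        "aur_low": 0.3,
        "oap_fraction": 0.7,
        "min_reads": 10,
        "count_no_expression": False,
    },
    "copies": {"min_identity": 0.8, "min_coverage": 0.8, "family_fraction": 0.25},
    "synteny": {"min_dots": 7, "max_gap": 15, "include_self": "always"},
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: Path) -> pd.DataFrame:
    with Path(path).open() as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", header=None, names=header)


def _file_digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    pass


class Pipeline:
    def __init__(self, config: dict, outdir: str | Path, seed: int | None = None):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = seed
        self._state_dir = self.outdir / ".stage"
        self._state_dir.mkdir(exist_ok=True)

    # -- resumability ------------------------------------------------------
    def _stage_key(self, stage: str, params: dict, inputs: list[Path]) -> str:
        payload = {
            "params": params,
            "inputs": {str(p): _file_digest(p) for p in sorted(inputs)},
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()

    def _skip(self, stage: str, key: str, outputs: list[Path]) -> bool:
        state = self._state_dir / f"{stage}.json"
        if not state.exists() or not all(p.exists() for p in outputs):
            return False
        return json.loads(state.read_text()).get("key") == key

    def _done(self, stage: str, key: str) -> None:
        (self._state_dir / f"{stage}.json").write_text(json.dumps({"key": key}))

    def _require(self, stage: str, *paths: Path) -> None:
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise PipelineError(
                f"stage '{stage}' is missing upstream outputs: {', '.join(missing)}"
            )

    # -- shared accessors --------------------------------------------------
    @property
    def simdir(self) -> Path:
        return self.outdir / "sim"

    def _species(self) -> list[str]:
        return sorted(
            p.name.split(".")[0] for p in self.simdir.glob("*.genome.fa")
        )

    def _load_catalog(self) -> cat.MirnaCatalog:
        merged = cat.MirnaCatalog()
        for sp in self._species():
            part = cat.load_catalog(
                self.simdir / f"{sp}.genome.fa",
                self.simdir / f"{sp}.mirna.gff3",
                self.simdir / "families.tsv",
                species_id=sp,
            )
            merged = merged.merge(part)
        return merged

    def _samples(self) -> list[cat.SampleMeta]:
        return cat.load_sample_sheet(self.simdir / "samples.tsv")

    def _pref_cfg(self) -> preference.PreferenceConfig:
        return preference.PreferenceConfig(**self.config["preference"])

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        sim_overrides = self.config.get("simulation")
        if sim_overrides is None:
            log.info("simulate: no simulation block, expecting external inputs")
            return
        params = dict(sim_overrides)
        if self.seed is not None:
            params["seed"] = self.seed
        if "read_len_range" in params:
            params["read_len_range"] = tuple(params["read_len_range"])
        key = self._stage_key("simulate", params, [])
        marker = self.simdir / "truth.json"
        if self._skip("simulate", key, [marker]):
            log.info("simulate: up to date, skipping")
            return
        cfg = simulate.SimConfig(**params)
        sim = simulate.simulate_genome(cfg)
        simulate.simulate_reads(sim)
        sim.write(self.simdir)
        log.info(
            "simulate: %d chromosomes, %d loci, %d samples (seed=%d)",
            len(sim.truth.chromosomes) * len(sim.truth.species),
            len(sim.catalog.loci),
            len(sim.truth.samples),
            cfg.seed,
        )
        self._done("simulate", key)

    def stage_quantify(self) -> None:
        params = self.config["quantify"]
        sheet = self.simdir / "samples.tsv"
        self._require("quantify", sheet, self.simdir / "families.tsv")
        samples = cat.load_sample_sheet(sheet)
        fastqs = {
            s.sample_id: self.simdir / f"reads_{s.sample_id}.fastq" for s in samples
        }
        self._require("quantify", *fastqs.values())
        key = self._stage_key("quantify", params, [sheet, *fastqs.values()])
        out = self.outdir / "arm_counts.tsv"
        if self._skip("quantify", key, [out]):
            log.info("quantify: up to date, skipping")
            return
        catalog = self._load_catalog()
        # reads are mapped against their own species' hairpins only
        tables = []
        stats: dict[str, quantify.FilterStats] = {}
        for sp in catalog.species:
            sp_fastqs = {
                s.sample_id: fastqs[s.sample_id]
                for s in samples
                if s.species_id == sp
            }
            if not sp_fastqs:
                continue
            sp_counts, sp_stats = quantify.quantify_samples(
                sp_fastqs,
                catalog.subset_species(sp),
                policy=params["policy"],
                max_mismatches=params["max_mismatches"],
                min_mean_phred=params["min_mean_phred"],
                min_len=params["min_len"],
                max_len=params["max_len"],
            )
            tables.append(sp_counts)
            stats.update(sp_stats)
        counts = pd.concat(tables, ignore_index=True)
        write_tsv(counts, out)
        for sample_id, st in stats.items():
            log.info(
                "quantify %s: %d reads in, %d kept (%d quality, %d length fails)",
                sample_id,
                st.n_input,
                st.n_kept,
                st.n_quality_fail,
                st.n_length_fail,
            )
        self._done("quantify", key)

    def stage_arm_prefs(self) -> None:
        params = self.config["preference"]
        counts_path = self.outdir / "arm_counts.tsv"
        self._require("arm_prefs", counts_path)
        key = self._stage_key("arm_prefs", params, [counts_path])
        calls_out = self.outdir / "arm_calls.tsv"
        oap_out = self.outdir / "oap.tsv"
        if self._skip("arm_prefs", key, [calls_out, oap_out]):
            log.info("arm_prefs: up to date, skipping")
            return
        cfg = self._pref_cfg()
        counts = read_tsv(counts_path)
        calls = preference.calls_from_count_table(counts, cfg)
        write_tsv(calls, calls_out)
        rows = []
        for locus_id, grp in calls.groupby("locus_id"):
            call_objs = [
                preference.ArmCall(r.locus_id, r.sample_id, r.aur, r.label)
                for r in grp.itertuples(index=False)
            ]
            rec = preference.overall_arm_preference(call_objs, cfg)
            rows.append(
                {
                    "locus_id": locus_id,
                    "oap": rec.oap,
                    "support_fraction": rec.support_fraction,
                    "n_informative_samples": rec.n_informative_samples,
                }
            )
        write_tsv(pd.DataFrame(rows), oap_out)
        log.info("arm_prefs: %d loci called", len(rows))
        self._done("arm_prefs", key)

    def _family_oaps(self, counts: pd.DataFrame):
        catalog = self._load_catalog()
        locus_info = {
            lid: (l.family_id, l.species_id) for lid, l in catalog.loci.items()
        }
        return preference.family_oaps_from_counts(
            counts, locus_info, self._pref_cfg()
        )

    def stage_switch(self) -> None:
        params = self.config["preference"]
        counts_path = self.outdir / "arm_counts.tsv"
        calls_path = self.outdir / "arm_calls.tsv"
        self._require("switch", counts_path, calls_path)
        key = self._stage_key("switch", params, [counts_path, calls_path])
        sw_out = self.outdir / "switches.tsv"
        mx_out = self.outdir / "preference_matrix.tsv"
        if self._skip("switch", key, [sw_out, mx_out]):
            log.info("switch: up to date, skipping")
            return
        counts = read_tsv(counts_path)
        fam_oaps, para_oaps = self._family_oaps(counts)
        events, matrix, uncallable = preference.detect_species_switching(fam_oaps)

        calls = read_tsv(calls_path)
        calls_by_locus = {
            lid: [
                preference.ArmCall(r.locus_id, r.sample_id, r.aur, r.label)
                for r in grp.itertuples(index=False)
            ]
            for lid, grp in calls.groupby("locus_id")
        }
        within: list[preference.SwitchEvent] = []
        for fam in sorted(para_oaps):
            for sp in sorted(para_oaps[fam]):
                within.extend(
                    preference.detect_within_species_switching(
                        {}, {fam: para_oaps[fam][sp]}
                    )
                )
        within.extend(preference.detect_within_species_switching(calls_by_locus))

        rows = [
            {
                "kind": e.kind,
                "entity_a": e.entity_a,
                "entity_b": e.entity_b,
                "arm_a": e.arm_a,
                "arm_b": e.arm_b,
            }
            for e in events + within
        ]
        write_tsv(
            pd.DataFrame(
                rows, columns=["kind", "entity_a", "entity_b", "arm_a", "arm_b"]
            ),
            sw_out,
        )
        matrix_out = matrix.reset_index()
        write_tsv(matrix_out, mx_out)
        log.info(
            "switch: %d species switches, %d within-species events, %d uncallable pairs",
            len(events),
            len(within),
            len(uncallable),
        )
        self._done("switch", key)

    def stage_conserve(self) -> None:
        counts_path = self.outdir / "arm_counts.tsv"
        self._require("conserve", counts_path, self.simdir / "families.tsv")
        key = self._stage_key(
            "conserve", self.config["preference"], [counts_path]
        )
        cons_out = self.outdir / "arm_conservation.tsv"
        conc_out = self.outdir / "concordance.json"
        if self._skip("conserve", key, [cons_out, conc_out]):
            log.info("conserve: up to date, skipping")
            return
        catalog = self._load_catalog()
        results = fates.conservation_by_family(catalog)
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "family_id": r.family_id,
                        "species_id": r.species_id,
                        "n_paralogues": r.n_paralogues,
                        "score_5p": r.score_5p,
                        "score_3p": r.score_3p,
                        "conserved_arm": r.conserved_arm,
                    }
                    for r in results
                ],
                columns=[
                    "family_id",
                    "species_id",
                    "n_paralogues",
                    "score_5p",
                    "score_3p",
                    "conserved_arm",
                ],
            ),
            cons_out,
        )
        counts = read_tsv(counts_path)
        _, para_oaps = self._family_oaps(counts)
        summary = fates.conserved_vs_dominant(results, para_oaps)
        conc_out.write_text(
            json.dumps(
                {
                    "n_assessed": summary.n_assessed,
                    "n_concordant": summary.n_concordant,
                    "fraction": summary.fraction,
                    "p_value": summary.p_value,
                    "assessed_families": summary.assessed_families,
                },
                indent=1,
                sort_keys=True,
            )
        )
        log.info(
            "conserve: %d families scored, %d/%d concordant",
            len(results),
            summary.n_concordant,
            summary.n_assessed,
        )
        self._done("conserve", key)

    def stage_copies(self) -> None:
        params = self.config["copies"]
        self._require("copies", self.simdir / "families.tsv")
        genome_paths = [self.simdir / f"{sp}.genome.fa" for sp in self._species()]
        self._require("copies", *genome_paths)
        key = self._stage_key("copies", params, genome_paths)
        out = self.outdir / "copy_number.tsv"
        rounds_out = self.outdir / "rounds_copies.json"
        if self._skip("copies", key, [out, rounds_out]):
            log.info("copies: up to date, skipping")
            return
        catalog = self._load_catalog()
        genomes = {
            sp: fates.GenomeSearcher.from_fasta(self.simdir / f"{sp}.genome.fa")
            for sp in self._species()
        }
        table = fates.copy_number_table(
            catalog,
            genomes,
            min_identity=params["min_identity"],
            min_coverage=params["min_coverage"],
        )
        write_tsv(table, out)
        inference = fates.infer_rounds_from_copies(
            table, family_fraction=params["family_fraction"]
        )
        rounds_out.write_text(json.dumps(inference, indent=1, sort_keys=True))
        log.info("copies: inferred %d round(s) from copy numbers", inference["estimate"])
        self._done("copies", key)

    def stage_synteny(self) -> None:
        params = self.config["synteny"]
        species = self._species()
        if not species:
            raise PipelineError("stage 'synteny' is missing upstream outputs: sim/*.anchors.tsv")
        anchor_paths = [self.simdir / f"{sp}.anchors.tsv" for sp in species]
        self._require("synteny", *anchor_paths)
        key = self._stage_key("synteny", params, anchor_paths)
        blocks_out = self.outdir / "blocks.tsv"
        partners_out = self.outdir / "partner_counts.tsv"
        rounds_out = self.outdir / "rounds_synteny.json"
        if self._skip("synteny", key, [blocks_out, partners_out, rounds_out]):
            log.info("synteny: up to date, skipping")
            return
        per_species = {}
        block_rows = []
        partner_rows = []
        for sp, apath in zip(species, anchor_paths):
            anchors = synteny.read_anchors(apath)
            blocks = synteny.find_synteny_blocks(
                anchors, min_dots=params["min_dots"], max_gap=params["max_gap"]
            )
            chroms = sorted(
                {a.chrom_a for a in anchors} | {a.chrom_b for a in anchors}
            )
            summary = synteny.partner_counts(
                blocks, chroms, include_self=params["include_self"]
            )
            inference = synteny.infer_rounds_from_synteny(summary)
            per_species[sp] = {
                "estimate": inference["estimate"],
                "tied_estimates": inference["tied_estimates"],
                "n_blocks": len(blocks),
            }
            for blk in blocks:
                block_rows.append(
                    {
                        "species_id": sp,
                        "chrom_a": blk.chrom_a,
                        "chrom_b": blk.chrom_b,
                        "orientation": blk.orientation,
                        "n_anchors": blk.n_anchors,
                        "a_start": blk.anchors[0].index_a,
                        "a_end": blk.anchors[-1].index_a,
                    }
                )
            for rec in inference["per_chromosome"].itertuples(index=False):
                partner_rows.append(
                    {
                        "species_id": sp,
                        "chromosome": rec.chromosome,
                        "n_partners": rec.n_partners,
                        "inferred_rounds": rec.inferred_rounds,
                    }
                )
        write_tsv(
            pd.DataFrame(
                block_rows,
                columns=[
                    "species_id",
                    "chrom_a",
                    "chrom_b",
                    "orientation",
                    "n_anchors",
                    "a_start",
                    "a_end",
                ],
            ),
            blocks_out,
        )
        write_tsv(
            pd.DataFrame(
                partner_rows,
                columns=["species_id", "chromosome", "n_partners", "inferred_rounds"],
            ),
            partners_out,
        )
        estimate = max(v["estimate"] for v in per_species.values())
        rounds_out.write_text(
            json.dumps(
                {"estimate": estimate, "per_species": per_species},
                indent=1,
                sort_keys=True,
            )
        )
        log.info("synteny: inferred %d round(s) from partner counts", estimate)
        self._done("synteny", key)

    def stage_report(self) -> None:
        needed = [
            self.outdir / "copy_number.tsv",
            self.outdir / "rounds_copies.json",
            self.outdir / "rounds_synteny.json",
            self.outdir / "partner_counts.tsv",
            self.outdir / "switches.tsv",
            self.outdir / "concordance.json",
        ]
        self._require("report", *needed)
        key = self._stage_key("report", {}, needed)
        out = self.outdir / "report.json"
        if self._skip("report", key, [out]):
            log.info("report: up to date, skipping")
            return
        copies = read_tsv(self.outdir / "copy_number.tsv")
        hist = {
            sp: {
                str(k): int(v)
                for k, v in grp["n_loci"].value_counts().sort_index().items()
            }
            for sp, grp in copies.groupby("species_id")
        }
        gt4 = {
            sp: int((grp["n_loci"] > 4).sum())
            for sp, grp in copies.groupby("species_id")
        }
        partners = read_tsv(self.outdir / "partner_counts.tsv")
        switches = read_tsv(self.outdir / "switches.tsv")
        report = {
            "config": self.config,
            "seed": self.seed,
            "copy_number_histogram": hist,
            "families_gt4_copies": gt4,
            "inferred_rounds_copies": json.loads(
                (self.outdir / "rounds_copies.json").read_text()
            ),
            "inferred_rounds_synteny": json.loads(
                (self.outdir / "rounds_synteny.json").read_text()
            ),
            "partner_count_range": {
                sp: [int(grp["n_partners"].min()), int(grp["n_partners"].max())]
                for sp, grp in partners[partners["n_partners"] > 0].groupby(
                    "species_id"
                )
            },
            "switch_events": {
                kind: int(n)
                for kind, n in switches["kind"].value_counts().sort_index().items()
            }
            if len(switches)
            else {},
            "concordance": json.loads((self.outdir / "concordance.json").read_text()),
        }
        out.write_text(json.dumps(report, indent=1, sort_keys=True))
        log.info("report: written to %s", out)
        self._done("report", key)

    def run(self, only: list[str] | None = None) -> Path:
        stages = list(only) if only else list(STAGES)
        for stage in stages:
            if stage not in STAGES:
                raise PipelineError(f"unknown stage {stage!r}")
            log.info("=== stage %s ===", stage)
            getattr(self, f"stage_{stage}")()
        return self.outdir / "report.json"


def run_pipeline(
    config: dict | str | Path | None,
    outdir: str | Path,
    seed: int | None = None,
    only: list[str] | None = None,
) -> Path:
    """Run the pipeline (all stages, or a subset in order) and return the
    report path."""
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    return Pipeline(config, outdir, seed).run(only)
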