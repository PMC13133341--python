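"""End-to-end analysis recipes: thin, deterministic compositions of the
module operations, serialized as TSV report bundles.

Every output table carries a header line with the tool version, a hash
of the run configuration and the seed, so re-running a recipe with the
same inputs is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .core import GenomicInterval, PreconditionError, SignalTrack
from .breakpoints import (
    MetaProfile,
    merge_intervals,
    meta_profile,
    pairs_to_intervals,
    proximity_null_test,
    relative_distance_test,
    sample_random_intervals,
)
from .motifs import DEFAULT_MOTIFS, MotifSet, RELAXED_G4, STRINGENT_G4, G4Params
from .motifs import gc_content_track, motif_density_track, scan_g_quadruplexes
from .shm import (
    assign_transcriptional_strand,
    directional_signal_profile,
    filter_somatic_variants,
    select_cytidine_mutations,
)
from .signatures import (
    CLASS_LABELS,
    SignatureCatalog,
    fit_signature_exposures,
    trinucleotide_spectrum,
)
from .stats import bonferroni

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs by role plus per-module parameters for one recipe run."""

    inputs: Dict[str, str] = field(default_factory=dict)
    params: Dict[str, object] = field(default_factory=dict)
    out_dir: str = "."
    seed: int = 0

    def require(self, *roles: str) -> None:
        missing = [r for r in roles if r not in self.inputs]
        if missing:
            raise PreconditionError(f"missing input roles: {missing}")
        absent = [
            r for r in roles
            if not Path(self.inputs[r]).exists()
        ]
        if absent:
            raise PreconditionError(
                f"input files do not exist for roles: {absent}"
            )

    def param(self, key: str, default):
        return self.params.get(key, default)

    def config_hash(self) -> str:
        blob = json.dumps(
            {"inputs": self.inputs, "params": self.params, "seed": self.seed},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            inputs=data.get("inputs", {}),
            params=data.get("params", {}),
            out_dir=data.get("out_dir", "."),
            seed=int(data.get("seed", 0)),
        )


def _header(config: RunConfig) -> str:
    return (
        f"# breakscape {__version__}\tconfig={config.config_hash()}"
        f"\tseed={config.seed}\n"
    )


def _write_tsv(config: RunConfig, name: str, columns: Sequence[str],
               rows: Sequence[Sequence]) -> Path:
    out = Path(config.out_dir) / name
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        fh.write(_header(config))
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return out


def _profile_rows(profile: MetaProfile) -> List[List]:
    rows = []
    for i, off in enumerate(profile.offsets):
        bg = (
            f"{profile.background_mean[i]:.6g}"
            if profile.background_mean is not None
            else "NA"
        )
        rows.append([int(off), f"{profile.mean_signal[i]:.6g}", bg])
    return rows


def run_breakpoint_characterization(config: RunConfig) -> Dict[str, Path]:
    """Merged breakpoint regions, meta-profiles over supplied tracks and
    sequence-feature density tracks, with a shuffled background."""
    from .io import (
        read_bed, read_bedpe, read_bedgraph_track, read_fasta,
        write_bed, write_bedgraph,
    )

    config.require("genome", "breakpoints")
    genome = read_fasta(config.inputs["genome"])
    pairs = read_bedpe(config.inputs["breakpoints"])
    if not pairs:
        raise PreconditionError("breakpoints input contains no pairs")
    anchors = merge_intervals(pairs_to_intervals(pairs))
    bin_width = int(config.param("bin_width", 1000))
    half_window = int(config.param("half_window", 100_000))
    n_draws = int(config.param("n_draws", 100))
    outputs: Dict[str, Path] = {}
    out_regions = Path(config.out_dir) / "merged_regions.bed"
    out_regions.parent.mkdir(parents=True, exist_ok=True)
    write_bed(anchors, out_regions)
    outputs["merged_regions"] = out_regions

    draws = sample_random_intervals(anchors, genome, n_draws, config.seed)

    tracks: Dict[str, SignalTrack] = {}
    for role, path in config.inputs.items():
        if role.startswith("track:"):
            tracks[role.split(":", 1)[1]] = read_bedgraph_track(
                path, bin_width, genome
            )
    motif_set = MotifSet(dict(config.param("motifs", DEFAULT_MOTIFS)))
    tracks.update(motif_density_track(genome, motif_set, bin_width))
    tracks["gc"] = gc_content_track(genome, bin_width)
    g4_track = SignalTrack.zeros(bin_width, genome.lengths)
    for iv in scan_g_quadruplexes(genome, STRINGENT_G4):
        g4_track.values[iv.chrom][iv.start // bin_width] += 1.0 / bin_width
    tracks["g4_stringent"] = g4_track

    for name, track in tracks.items():
        profile = meta_profile(anchors, track, half_window, background=draws)
        outputs[f"profile_{name}"] = _write_tsv(
            config,
            f"profile_{name}.tsv",
            ["offset_bp", "mean_signal", "background_mean"],
            _profile_rows(profile),
        )
    return outputs


def run_proximity_suite(config: RunConfig) -> Dict[str, Path]:
    """Distance-to-feature distributions with shuffle-null Wilcoxon
    (Bonferroni-scaled across feature sets) and relative-distance
    chi-square tests."""
    from .io import read_bed, read_bedpe, read_fasta

    config.require("breakpoints")
    feature_roles = [r for r in config.inputs if r.startswith("features:")]
    if not feature_roles:
        raise PreconditionError("need at least one 'features:<name>' input")
    config.require(*feature_roles)
    if "genome" in config.inputs:
        genome = read_fasta(config.inputs["genome"])
        sizes = genome.lengths
    else:
        sizes = {
            k: int(v) for k, v in config.param("chrom_sizes", {}).items()
        }
        if not sizes:
            raise PreconditionError("need 'genome' input or chrom_sizes param")
    pairs = read_bedpe(config.inputs["breakpoints"])
    queries = pairs_to_intervals(pairs)
    n_draws = int(config.param("n_draws", 100))
    n_bins = int(config.param("reldist_bins", 10))
    rows = []
    dist_rows = []
    for role in feature_roles:
        name = role.split(":", 1)[1]
        features = read_bed(config.inputs[role])
        res = proximity_null_test(queries, features, sizes, n_draws, config.seed)
        p_adj = bonferroni(res.wilcoxon.p_value, len(feature_roles))
        rel = relative_distance_test(queries, features, n_bins)
        rows.append([
            name, f"{res.observed_median:.1f}", f"{res.null_median:.1f}",
            f"{res.wilcoxon.p_value:.4g}", f"{p_adj:.4g}",
            f"{rel.chi2.statistic:.4g}", f"{rel.chi2.p_value:.4g}",
        ])
        for d in res.observed_distances:
            dist_rows.append([name, "observed", d])
        for d in res.null_distances:
            dist_rows.append([name, "null", d])
    outputs = {
        "proximity_tests": _write_tsv(
            config, "proximity_tests.tsv",
            ["feature_set", "observed_median", "null_median",
             "wilcoxon_p", "wilcoxon_p_bonferroni", "reldist_chi2", "reldist_p"],
            rows,
        ),
        "distances": _write_tsv(
            config, "distances.tsv", ["feature_set", "kind", "distance_bp"],
            dist_rows,
        ),
    }
    return outputs


def run_shm_asymmetry(config: RunConfig) -> Dict[str, Path]:
    """Somatic filter -> cytidine selection -> strand assignment ->
    binomial bias test -> directional stranded-signal profiles."""
    from .io import read_bed, read_bedgraph_track, read_fasta, read_vcf_snvs

    variant_roles = sorted(r for r in config.inputs if r.startswith("variants:"))
    control_roles = sorted(r for r in config.inputs if r.startswith("controls:"))
    config.require("genes", *variant_roles, *control_roles)
    if not variant_roles:
        raise PreconditionError("need at least one 'variants:<sample>' input")
    per_sample = {
        r.split(":", 1)[1]: read_vcf_snvs(config.inputs[r], sample=r.split(":", 1)[1])
        for r in variant_roles
    }
    if all(len(v) == 0 for v in per_sample.values()):
        raise PreconditionError("variant inputs contain no SNVs")
    controls = {
        r.split(":", 1)[1]: read_vcf_snvs(config.inputs[r])
        for r in control_roles
    } or None
    somatic = filter_somatic_variants(per_sample, controls)
    pooled = [v for vs in somatic.values() for v in vs]
    cyt = select_cytidine_mutations(pooled)
    genes = read_bed(config.inputs["genes"])
    res = assign_transcriptional_strand(cyt, genes)
    rows = [[
        res.n_nontemplate, res.n_template, res.n_unassigned,
        f"{res.bias:.4f}" if res.n_nontemplate + res.n_template else "NA",
        f"{res.binomial.p_value:.4g}" if res.binomial else "NA",
    ]]
    outputs = {
        "strand_bias": _write_tsv(
            config, "strand_bias.tsv",
            ["n_nontemplate", "n_template", "n_unassigned", "bias", "binomial_p"],
            rows,
        )
    }
    if "track_plus" in config.inputs and "track_minus" in config.inputs:
        if "genome" in config.inputs:
            sizes = read_fasta(config.inputs["genome"]).lengths
        else:
            sizes = {k: int(v) for k, v in config.param("chrom_sizes", {}).items()}
        bin_width = int(config.param("bin_width", 100))
        half_window = int(config.param("half_window", 2000))
        track = read_bedgraph_track(
            [config.inputs["track_plus"], config.inputs["track_minus"]],
            bin_width, sizes,
        )
        profs = directional_signal_profile(cyt, track, half_window)
        rows = [
            [int(off), f"{profs.sense.mean_signal[i]:.6g}",
             f"{profs.antisense.mean_signal[i]:.6g}"]
            for i, off in enumerate(profs.sense.offsets)
        ]
        outputs["directional_profile"] = _write_tsv(
            config, "directional_profile.tsv",
            ["offset_bp", "sense_mean", "antisense_mean"], rows,
        )
    return outputs


def run_signature_fit(config: RunConfig) -> Dict[str, Path]:
    """One spectrum and exposure fit per (sample x region set)."""
    from .io import read_bed, read_fasta, read_vcf_snvs

    variant_roles = sorted(r for r in config.inputs if r.startswith("variants:"))
    config.require("genome", "catalog", *variant_roles)
    if not variant_roles:
        raise PreconditionError("need at least one 'variants:<sample>' input")
    genome = read_fasta(config.inputs["genome"])
    catalog = SignatureCatalog.from_tsv(config.inputs["catalog"])
    region_sets: Dict[str, Optional[List[GenomicInterval]]] = {"genome_wide": None}
    for role in config.inputs:
        if role.startswith("regions:"):
            region_sets[role.split(":", 1)[1]] = read_bed(config.inputs[role])
    spec_rows = []
    fit_rows = []
    for role in variant_roles:
        sample = role.split(":", 1)[1]
        variants = read_vcf_snvs(config.inputs[role], sample=sample)
        for rname, regions in region_sets.items():
            spectrum = trinucleotide_spectrum(variants, genome, regions)
            for label, count in zip(CLASS_LABELS, spectrum.counts):
                if count:
                    spec_rows.append([sample, rname, label, int(count)])
            if spectrum.n_used == 0:
                logger.warning("empty spectrum for %s / %s", sample, rname)
                continue
            fit = fit_signature_exposures(spectrum, catalog)
            for sig, w in fit.as_dict().items():
                fit_rows.append([
                    sample, rname, sig, f"{w:.4f}",
                    f"{fit.residual_norm:.4g}", spectrum.n_used, spectrum.n_skipped,
                ])
    return {
        "spectra": _write_tsv(
            config, "spectra.tsv",
            ["sample", "region_set", "class", "count"], spec_rows,
        ),
        "exposures": _write_tsv(
            config, "exposures.tsv",
            ["sample", "region_set", "signature", "weight",
             "residual_norm", "n_used", "n_skipped"], fit_rows,
        ),
    }
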