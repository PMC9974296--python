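"""Configuration, orchestration and provenance for running the analysis
stages singly or end-to-end.

A single global seed fans out to per-stage seeds through a fixed counter
offset, so any stage can be rerun on its own and reproduce byte-identical
artefacts. Every run writes a manifest listing each artefact with its SHA-256
hash and generating seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "STAGES"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "spectra": {
            # label, primary peak (nm, % height, nm width), secondary triple
            "groups": [
                ["parent1", 550.0, 30.0, 40.0, [450.0, 12.0, 15.0]],
                ["parent2", 510.0, 30.0, 40.0, [450.0, 12.0, 15.0]],
                ["hybrid", 575.0, 30.0, 40.0, None],
            ],
            "n_per_group": 10,
            "noise_sd": 0.5,
        },
        "nanostructure": {"patch": "gorget", "n_images": 11},
        "cross": {
            "n_loci": 1000,
            "n_parental_per_species": 4,
            "cross_type": "BC1_P1",
            "missing_rate": 0.0,
        },
        "tree": {"n_tips": 100, "total_depth": 40.0, "sigma2_true": 0.005, "n_axes": 3},
        "niche": {
            "grid_shape": [60, 80],
            "n_env_layers": 4,
            "n_occurrences": 100,
            "centre_a": [0.5, 0.0, 0.0, 0.5],
            "centre_b": [0.3, 0.2, 0.0, 0.3],
            "niche_sd": 0.55,
        },
    },
    "colour": {"n_boot": 1000, "weber": 0.1, "densities": [1.0, 2.0, 2.0, 4.0]},
    "optics": {
        "air_shape": "sphere",
        "top_platelet_solid": False,
        "lateral_fill": 1.0,
        "slice_thickness": 1.0,
        "angle_deg": 0.0,
    },
    "divergence": {},
    "rate": {"n_perm": 999},
    "ancestry": {"min_depth": 6, "min_quality": 20.0},
    "niche": {"coverage": 0.9, "n_reps": 99, "mode": "continuous"},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {where!r} must be a mapping")
            out[key] = _merge(defaults[key], val, where)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load and validate a YAML config; missing keys take defaults, unknown
    keys raise. ``path=None`` or an empty file yields the all-defaults
    config."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a YAML mapping")
    cfg = _merge(DEFAULT_CONFIG, user)
    logger.info("effective config: %s", json.dumps(cfg, default=str))
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg))


def _stage_seed(cfg: dict, counter: int) -> int:
    return (int(cfg["seed"]) * 1009 + counter) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, outdir: Path, seed: int) -> list[Path]:
    from . import synthetic_data as sd
    from .colour_vision import write_spectra

    c = cfg["simulate"]
    paths = []
    groups = tuple(
        (g[0], g[1], g[2], g[3], tuple(g[4]) if g[4] else None)
        for g in c["spectra"]["groups"]
    )
    spectra = sd.gen_spectra(
        sd.SpectrumGenSpec(
            groups=groups,
            n_per_group=c["spectra"]["n_per_group"],
            noise_sd=c["spectra"]["noise_sd"],
            seed=seed,
        )
    )
    all_spectra = [s for g in spectra.values() for s in g]
    write_spectra(all_spectra, outdir / "spectra.csv")
    paths.append(outdir / "spectra.csv")

    rows = []
    for taxon in ("branickii", "hybrid", "gularis"):
        means = sd.nanostructure_means(taxon, c["nanostructure"]["patch"])
        _, df = sd.gen_nanostructure(means, c["nanostructure"]["n_images"], seed=seed)
        df.insert(0, "taxon", taxon)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(outdir / "nanostructure.csv", index=False)
    paths.append(outdir / "nanostructure.csv")

    gm, truth = sd.gen_cross(
        sd.CrossGenSpec(seed=seed, **{k: v for k, v in c["cross"].items()})
    )
    sd.write_vcf(gm, outdir / "genotypes.vcf")
    pd.DataFrame(
        {"sample": gm.samples, "population": [gm.populations[s] for s in gm.samples]}
    ).to_csv(outdir / "popmap.csv", index=False)
    truth.to_csv(outdir / "cross_truth.csv", index=False)
    paths += [outdir / "genotypes.vcf", outdir / "popmap.csv", outdir / "cross_truth.csv"]

    tree, traits = sd.gen_tree_traits(sd.TreeTraitGenSpec(seed=seed, **c["tree"]))
    (outdir / "tree.nwk").write_text(tree.as_string(schema="newick"))
    traits.to_csv(outdir / "tip_traits.csv")
    paths += [outdir / "tree.nwk", outdir / "tip_traits.csv"]

    nc = c["niche"]
    d = nc["n_env_layers"]
    cov = (np.eye(d) * nc["niche_sd"] ** 2).tolist()
    stack, occ, poly = sd.gen_niche_system(
        sd.NicheGenSpec(
            grid_shape=tuple(nc["grid_shape"]),
            n_env_layers=d,
            niche_centre={"speciesA": nc["centre_a"], "speciesB": nc["centre_b"]},
            niche_cov={"speciesA": cov, "speciesB": cov},
            n_occurrences=nc["n_occurrences"],
            seed=seed,
        )
    )
    stack.write(outdir / "env")
    sd.write_occurrences(occ, outdir / "occurrences.csv")
    sd.write_m_polygons(poly, outdir / "m_polygons.geojson")
    paths += sorted((outdir / "env").glob("*.asc"))
    paths += [outdir / "occurrences.csv", outdir / "m_polygons.geojson"]
    return paths


def _group_of(specimen_id: str) -> str:
    return specimen_id.rsplit("_", 1)[0]


def _stage_colour(cfg, outdir: Path, seed: int) -> list[Path]:
    from . import colour_vision as cv

    c = cfg["colour"]
    dens = dict(zip("usml", c["densities"]))
    vs = cv.VisualSystem.uvs_template(densities=dens, weber=c["weber"])
    spectra = cv.read_spectra(outdir / "spectra.csv")
    groups: dict[str, list] = {}
    for s in spectra:
        groups.setdefault(_group_of(s.specimen_id), []).append(s)
    labels = sorted(groups)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = cv.bootstrap_group_distance(
                groups[a], groups[b], vs, n_boot=c["n_boot"], seed=seed
            )
            rows.append((a, b, d.delta_s, d.ci_low, d.ci_high, d.significant))
    pd.DataFrame(
        rows, columns=["group_a", "group_b", "jnd", "ci_low", "ci_high", "significant"]
    ).to_csv(outdir / "colour_distances.csv", index=False)

    coords = []
    for s in spectra:
        p = cv.noise_scaled_coords(cv.quantum_catches(s, vs), vs)
        coords.append((s.specimen_id, _group_of(s.specimen_id), *p.xyz))
    pd.DataFrame(coords, columns=["specimen", "group", "x", "y", "z"]).to_csv(
        outdir / "colour_coords.csv", index=False
    )
    return [outdir / "colour_distances.csv", outdir / "colour_coords.csv"]


def _stage_optics(cfg, outdir: Path, seed: int) -> list[Path]:
    from . import feather_optics as fo

    c = cfg["optics"]
    nano = pd.read_csv(outdir / "nanostructure.csv")
    spec_rows, summary = [], []
    for _, row in nano.iterrows():
        p = fo.params_from_means(
            row,
            air_shape=c["air_shape"],
            top_platelet_solid=c["top_platelet_solid"],
            lateral_fill=c["lateral_fill"],
        )
        sim = fo.simulate_feather_spectrum(
            p, slice_thickness=c["slice_thickness"], angle_deg=c["angle_deg"]
        )
        summary.append(
            (row["taxon"], sim.hue_nm, fo.secondary_peak_prominence(sim))
        )
        spec_rows.append(pd.Series(sim.reflectance, name=f"{row['taxon']}_{_}"))
    out = pd.concat(
        [pd.Series(sim.wavelengths, name="wavelength_nm"), *spec_rows], axis=1
    )
    out.to_csv(outdir / "optics_spectra.csv", index=False)
    pd.DataFrame(summary, columns=["taxon", "hue_nm", "band_prominence"]).to_csv(
        outdir / "optics_summary.csv", index=False
    )
    return [outdir / "optics_spectra.csv", outdir / "optics_summary.csv"]


def _stage_divergence(cfg, outdir: Path, seed: int) -> list[Path]:
    from .trait_divergence import average_pairwise_divergence

    coords = pd.read_csv(outdir / "colour_coords.csv")
    mapping = {"parent1": "parent1", "parent2": "parent2", "hybrid": "hybrid"}
    coords["group"] = coords["group"].map(mapping)
    res = average_pairwise_divergence(
        coords[["group", "x", "y", "z"]], group_col="group"
    )
    res.per_pair.to_csv(outdir / "divergence_pairs.csv", index=False)
    pd.DataFrame(
        [{"d_parent_bias": res.d_parent_bias, "d_mismatch": res.d_mismatch}]
    ).to_csv(outdir / "divergence.csv", index=False)
    return [outdir / "divergence_pairs.csv", outdir / "divergence.csv"]


def _stage_rate(cfg, outdir: Path, seed: int) -> list[Path]:
    from . import phylo_rate as pr

    tree = pr.read_tree(str(outdir / "tree.nwk"))
    traits = pd.read_csv(outdir / "tip_traits.csv", index_col="tip")
    est = pr.multivariate_rate(tree, traits)
    sig = pr.blomberg_K(tree, traits, n_perm=cfg["rate"]["n_perm"], seed=seed)
    report = {
        "sigma2": est.sigma2,
        "n_nodes": est.n_nodes,
        "K": sig.K,
        "p": sig.p_value,
        "n_permutations": sig.n_permutations,
        "seed": seed,
    }
    (outdir / "rate.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame({"squared_contrast": est.squared_contrasts}).to_csv(
        outdir / "contrasts.csv", index=False
    )
    return [outdir / "rate.json", outdir / "contrasts.csv"]


def _stage_ancestry(cfg, outdir: Path, seed: int) -> list[Path]:
    from . import hybrid_ancestry as ha

    c = cfg["ancestry"]
    pops = pd.read_csv(outdir / "popmap.csv")
    popmap = dict(zip(pops["sample"], pops["population"]))
    gm = ha.read_vcf(outdir / "genotypes.vcf", popmap)
    n_input = gm.n_loci
    gm = ha.filter_snps(
        gm, ha.FilterConfig(min_depth=c["min_depth"], min_quality=c["min_quality"])
    )
    n_filtered = gm.n_loci
    gm = ha.diagnostic_loci(gm)
    reports = []
    for s, p in popmap.items():
        if p != "focal":
            continue
        est = ha.hybrid_index(gm, s)
        label, _dists = ha.classify_hybrid(est.h, est.heterozygosity)
        reports.append(
            {
                "individual": s,
                "n_input_loci": n_input,
                "n_filtered": n_filtered,
                "n_diagnostic": gm.n_loci,
                "h": est.h,
                "ci": [est.ci_low, est.ci_high],
                "het": est.heterozygosity,
                "class": label,
            }
        )
    (outdir / "ancestry.json").write_text(json.dumps(reports, indent=2))
    return [outdir / "ancestry.json"]


def _stage_niche(cfg, outdir: Path, seed: int) -> list[Path]:
    from . import niche_model as nm
    from .synthetic_data import read_m_polygons, read_occurrences

    c = cfg["niche"]
    stack = nm.EnvRasterStack.read(outdir / "env")
    occ = {
        sp: nm.extract_env(o, stack)
        for sp, o in read_occurrences(outdir / "occurrences.csv").items()
    }
    polys = read_m_polygons(outdir / "m_polygons.geojson")
    (a, occ_a), (b, occ_b) = sorted(occ.items())
    report = {"species": [a, b], "n_reps": c["n_reps"]}
    paths = []
    for direction, (o1, o2, m1) in {
        f"{a}_vs_{b}": (occ_a, occ_b, polys[a]),
        f"{b}_vs_{a}": (occ_b, occ_a, polys[b]),
    }.items():
        res = nm.background_similarity_test(
            o1, o2, m1, stack,
            n_reps=c["n_reps"], coverage=c["coverage"], seed=seed, mode=c["mode"],
        )
        report[direction] = {"D_obs": res.D_observed, "p": res.p_value}
    for sp, o in occ.items():
        model = nm.fit_mve(o.env, coverage=c["coverage"], seed=seed)
        smap = nm.suitability_map(model, stack)
        nm.write_ascii_grid(outdir / f"suitability_{sp}.asc", smap.suitability, stack.grid)
        nm.write_ascii_grid(
            outdir / f"binary_{sp}.asc", smap.binary.astype(float), stack.grid
        )
        paths += [outdir / f"suitability_{sp}.asc", outdir / f"binary_{sp}.asc"]
    (outdir / "niche.json").write_text(json.dumps(report, indent=2))
    return [outdir / "niche.json", *paths]


STAGES = {
    "simulate": _stage_simulate,
    "colour": _stage_colour,
    "optics": _stage_optics,
    "divergence": _stage_divergence,
    "rate": _stage_rate,
    "ancestry": _stage_ancestry,
    "niche": _stage_niche,
}

_DEPS = {
    "colour": ["spectra.csv"],
    "optics": ["nanostructure.csv"],
    "divergence": ["colour_coords.csv"],
    "rate": ["tree.nwk", "tip_traits.csv"],
    "ancestry": ["genotypes.vcf", "popmap.csv"],
    "niche": ["occurrences.csv", "m_polygons.geojson"],
}


def run_pipeline(cfg: dict, outdir, stages=None) -> list[dict]:
    """Run the requested stages in dependency order; returns (and writes)
    the artefact manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = list(STAGES) if stages is None else list(stages)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in wanted]
    manifest = []
    for counter, name in enumerate(ordered):
        for dep in _DEPS.get(name, []):
            if not (outdir / dep).exists():
                raise FileNotFoundError(
                    f"stage {name!r} needs {dep!r}; run the simulate stage "
                    "or provide the file"
                )
        seed = _stage_seed(cfg, list(STAGES).index(name))
        logger.info("running stage %s (seed %d)", name, seed)
        for p in STAGES[name](cfg, outdir, seed):
            manifest.append(
                {"stage": name, "artifact": p.name, "sha256": _sha256(p), "seed": seed}
            )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
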