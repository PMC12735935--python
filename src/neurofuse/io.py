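"""File I/O, run configuration and end-to-end pipeline orchestration.

Volumes are NIfTI-1 (float32 maps, int16 atlas labels, affine preserved);
diffusion tables use the FSL bval/bvec dialect (one space-separated row of
b-values; three rows of direction components); tabular outputs are CSV with
header rows; configuration is YAML.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import asl as asl_mod
from . import fusion as fusion_mod
from . import icc as icc_mod
from . import ivim as ivim_mod
from . import roi as roi_mod
from . import stats as stats_mod
from . import synthetic as syn

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_bval_bvec",
    "read_bval_bvec",
    "RunConfig",
    "run_end_to_end",
]

logger = logging.getLogger(__name__)

MODALITIES = ("CBF", "F_p", "F_f", "F_s", "D_s")


def save_nifti(path, data, affine=None, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 (default float32; pass int16 for labels)."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))


def load_nifti(path):
    """Read a NIfTI volume; returns ``(data, affine)`` with float64 data."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_bval_bvec(scheme: syn.AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write the acquisition scheme in the FSL bval/bvec text dialect."""
    b = scheme.b_per_volume
    vecs = scheme.bvec_per_volume
    Path(bval_path).write_text(" ".join(f"{v:g}" for v in b) + "\n")
    lines = [" ".join(f"{v:.8f}" for v in vecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def read_bval_bvec(bval_path, bvec_path, n_volumes: int | None = None):
    """Read FSL-dialect tables; returns ``(bvals (n,), bvecs (n, 3))``.

    Raises if the two tables disagree or do not match ``n_volumes``.
    """
    bvals = np.loadtxt(str(bval_path), ndmin=1)
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bvec table shape {bvecs.shape} does not match {bvals.size} b-values"
        )
    if n_volumes is not None and bvals.size != n_volumes:
        raise ValueError(
            f"b table has {bvals.size} entries but the series has "
            f"{n_volumes} volumes"
        )
    return bvals, bvecs


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort pipeline run."""

    seed: int = 0
    out_dir: str = "neurofuse_run"
    # cohort
    n_hc: int = 24
    n_mtbi: int = 19
    n_retest: int = 11
    # phantom / acquisition (desk-scale grid keeping the 90-region structure)
    grid_shape: tuple = (10, 10, 6)
    n_regions: int = 90
    dwi_snr: float = 100.0
    asl_snr: float = 200.0
    asl_pairs: int = 8
    group_effect: dict = field(default_factory=lambda: {
        "CBF": -0.15, "F_p": -0.15, "F_s": +0.03,
    })
    # fusion
    n_components: int = 3
    include_gose: bool = True
    # misc
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _fit_subject_maps(truth, scheme, cohort, dwi_snr, asl_snr, asl_pairs, seeds):
    """Forward-simulate and fit every subject; returns maps[modality][subject]."""
    b = scheme.b_per_volume
    maps: dict[str, dict[str, np.ndarray]] = {m: {} for m in MODALITIES}
    for i, subject in enumerate(cohort["subject"]):
        dwi = syn.simulate_dwi(
            truth[subject], scheme, snr=dwi_snr, noise_model="rician",
            seed=int(seeds[2 * i]),
        )
        pmap = ivim_mod.fit_triexp_volume(dwi, b)
        series = syn.simulate_asl(
            truth[subject]["CBF"], n_pairs=asl_pairs, snr=asl_snr,
            seed=int(seeds[2 * i + 1]),
        )
        dm = asl_mod.split_and_subtract(series)
        cbf = asl_mod.quantify_cbf(dm, series.m0, series.constants)
        fitted = {"CBF": cbf, "F_p": pmap.f_p, "F_f": pmap.f_f,
                  "F_s": pmap.f_s, "D_s": pmap.d_s}
        for m in MODALITIES:
            maps[m][subject] = fitted[m]
    return maps


def run_end_to_end(config: RunConfig) -> Path:
    """Run the whole pipeline on a synthetic cohort.

    simulate -> fit IVIM -> fit CBF -> ROI features -> fusion -> statistics
    -> test-retest ICC, writing every artifact plus JSON run metadata under
    ``config.out_dir``.  Identical config and seed give identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    for sub in ("volumes", "features", "fusion", "stats", "icc"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4096) % (2**31)

    cohort = syn.make_cohort(config.n_hc, config.n_mtbi, config.n_retest,
                             seed=int(seeds[0]))
    cohort.to_csv(out / "subjects.csv", index=False)

    spec = syn.PhantomSpec(
        shape=config.grid_shape, n_regions=config.n_regions,
        group_effect=dict(config.group_effect), snr=config.dwi_snr,
        seed=int(seeds[1]),
    )
    truth, atlas = syn.generate_phantom(spec, cohort)
    save_nifti(out / "volumes" / "atlas.nii.gz", atlas, dtype=np.int16)

    scheme = syn.build_acquisition_scheme()
    write_bval_bvec(scheme, out / "volumes" / "dwi.bval",
                    out / "volumes" / "dwi.bvec")

    maps = _fit_subject_maps(
        truth, scheme, cohort, config.dwi_snr, config.asl_snr,
        config.asl_pairs, seeds[10:],
    )
    first = cohort["subject"].iloc[0]
    for m in MODALITIES:
        save_nifti(out / "volumes" / f"{first}_{m}.nii.gz", maps[m][first])

    # ROI feature blocks
    subjects = list(cohort["subject"])
    zblocks = {}
    for m in MODALITIES:
        block = roi_mod.assemble_block(maps[m], atlas, m, subjects=subjects)
        zb = roi_mod.zscore_block(block)
        zb.data.to_csv(out / "features" / f"{m}.csv")
        zblocks[m] = zb

    # fusion and group statistics (imaging blocks only)
    fus_cfg = fusion_mod.FusionConfig(
        n_components=config.n_components, ica_seed=int(seeds[2]),
    )
    result = fusion_mod.fuse(list(zblocks.values()), fus_cfg)
    scores = result.ic_scores
    scores.to_csv(out / "fusion" / "ic_scores.csv")
    pd.DataFrame(result.ave, columns=result.block_names,
                 index=[f"comp{j + 1}" for j in range(result.ave.shape[0])]
                 ).to_csv(out / "fusion" / "ave.csv")
    for b, name in enumerate(result.block_names):
        pd.DataFrame(result.rgcca.weights[b],
                     index=zblocks[name].data.columns,
                     columns=[f"comp{j + 1}" for j in range(config.n_components)]
                     ).to_csv(out / "fusion" / f"weights_{name}.csv")

    group_tab = stats_mod.compare_groups(scores, cohort["group"].to_numpy())
    group_tab.to_csv(out / "stats" / "ic_group_ttests.csv", index=False)
    corr = stats_mod.correlate_components_rois(scores, zblocks)
    corr.to_csv(out / "stats" / "ic_roi_correlations.csv", index=False)
    stats_mod.top_regions(corr, 5).to_csv(
        out / "stats" / "ic_roi_top5.csv", index=False)
    demo = stats_mod.demographics(cohort)
    (out / "stats" / "demographics.json").write_text(json.dumps({
        "chi2": demo["chi2"], "chi2_p": demo["chi2_p"],
        "continuous": demo["continuous"],
    }, indent=2, default=str))

    # GOS-E fusion (injured group only, sixth behavioural block)
    if config.include_gose:
        tbi = cohort[cohort["group"] == "mTBI"]
        tbi_ids = list(tbi["subject"])
        gose_block = roi_mod.BlockMatrix(
            modality="GOSE",
            data=pd.DataFrame({"gose": tbi["gose"].to_numpy()},
                              index=pd.Index(tbi_ids, name="subject")),
        )
        tbi_blocks = []
        for m in MODALITIES:
            sub = roi_mod.BlockMatrix(modality=m,
                                      data=zblocks[m].data.loc[tbi_ids])
            tbi_blocks.append(roi_mod.zscore_block(sub))
        tbi_blocks.append(roi_mod.zscore_block(gose_block))
        gose_res = fusion_mod.fuse(tbi_blocks, fusion_mod.FusionConfig(
            n_components=config.n_components, ica_seed=int(seeds[3])))
        gose_scores = gose_res.ic_scores
        gose_scores.to_csv(out / "fusion" / "ic_scores_gose.csv")
        gose_tab = stats_mod.correlate_gose(gose_scores,
                                            tbi["gose"].to_numpy())
        gose_tab.to_csv(out / "stats" / "ic_gose_correlations.csv", index=False)
        roi_tab = stats_mod.correlate_gose_rois(
            {m: roi_mod.BlockMatrix(modality=m,
                                    data=zblocks[m].data.loc[tbi_ids])
             for m in MODALITIES},
            tbi["gose"].to_numpy(),
        )
        roi_tab.to_csv(out / "stats" / "roi_gose_correlations.csv", index=False)

    # test-retest ICC on the retest subset (second visit = new noise draw)
    retest = cohort[cohort["retest"]]
    if len(retest) >= 3:
        scheme_b = scheme.b_per_volume
        rows = []
        v2_maps = {m: {} for m in MODALITIES}
        for i, subject in enumerate(retest["subject"]):
            dwi = syn.simulate_dwi(
                truth[subject], scheme, snr=config.dwi_snr,
                noise_model="rician", seed=int(seeds[2000 + 2 * i]))
            pmap = ivim_mod.fit_triexp_volume(dwi, scheme_b)
            series = syn.simulate_asl(
                truth[subject]["CBF"], n_pairs=config.asl_pairs,
                snr=config.asl_snr, seed=int(seeds[2000 + 2 * i + 1]))
            cbf = asl_mod.quantify_cbf(
                asl_mod.split_and_subtract(series), series.m0, series.constants)
            fitted = {"CBF": cbf, "F_p": pmap.f_p, "F_f": pmap.f_f,
                      "F_s": pmap.f_s, "D_s": pmap.d_s}
            for m in MODALITIES:
                v2_maps[m][subject] = fitted[m]
        for m in MODALITIES:
            v1 = np.stack([maps[m][s] for s in retest["subject"]])
            v2 = np.stack([v2_maps[m][s] for s in retest["subject"]])
            res = icc_mod.icc_map(v1, v2, variant="consistency")
            save_nifti(out / "icc" / f"icc_{m}.nii.gz", res.icc)
            rows.append({"metric": m, "icc_mean": res.mean, "icc_sd": res.sd,
                         "variant": res.variant})
        pd.DataFrame(rows).to_csv(out / "icc" / "icc_summary.csv", index=False)

    config.save(out / "config.yaml")
    meta = {
        "config": config.to_dict(),
        "versions": {
            "numpy": np.__version__,
            "nibabel": nib.__version__,
            "pandas": pd.__version__,
        },
        "n_subjects": len(cohort),
        "n_ics": int(result.jica.n_ic),
        "fdr_families": {
            "ic_group_ttests": "across ICs",
            "ic_roi_correlations": "within IC x modality (ROI count)",
            "gose": "across ICs / within modality",
        },
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    logger.info("pipeline complete: %d subjects, %d ICs", len(cohort),
                result.jica.n_ic)
    return out
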