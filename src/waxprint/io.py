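"""Format readers/writers, configuration and the pipeline orchestrator.

Canonical interchange is plain CSV: runs in long format (scan_time, mz,
intensity), TIS matrices wide (rows = m/z, columns = sample ids), metadata
one row per sample. mzML is supported as a read/write convenience:
centroided, unit-mass spectra with 64-bit float arrays, written and parsed
with a compact namespace-aware XML layer using the standard PSI-MS
controlled-vocabulary accessions.

``run_pipeline`` ties the stages together: simulate -> TIS assembly ->
exploratory HCA/PCA -> response-surface fit on the bundled headspace study
(or user-supplied responses) -> supervised training, writing per-stage
artifacts, seeds and SHA-256 hashes into a JSON report.
"""

from __future__ import annotations

import base64
import hashlib
import json
import struct
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lxml import etree
from pydantic import BaseModel, ConfigDict

from . import cluster, learn, simulate, tis
from .datasets import load_headspace_bbd
from .doe import ResponseSurfaceModel, grid_scan

__all__ = [
    "read_run",
    "write_run",
    "read_run_csv",
    "write_run_csv",
    "read_run_mzml",
    "write_run_mzml",
    "PipelineConfig",
    "run_pipeline",
    "PipelineError",
]


# --------------------------------------------------------------------------
# long-CSV run format
# --------------------------------------------------------------------------
def write_run_csv(run: tis.GcmsRun, path: str | Path) -> None:
    """Long format: one row per (scan_time, mz) with non-zero intensity."""
    scan_idx, mz_idx = np.nonzero(run.intensities)
    df = pd.DataFrame(
        {
            "scan_time": run.scan_times[scan_idx],
            "mz": run.mz_axis[mz_idx],
            "intensity": run.intensities[scan_idx, mz_idx],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# sample_id={run.sample_id}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_run_csv(path: str | Path) -> tis.GcmsRun:
    path = Path(path)
    sample_id = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# sample_id="):
            sample_id = first.split("=", 1)[1].strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    required = {"scan_time", "mz", "intensity"}
    if df.empty or not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected non-empty CSV with columns {sorted(required)}"
        )
    times = np.unique(df["scan_time"].to_numpy(dtype=float))
    mzs = np.unique(df["mz"].to_numpy())
    t_index = {t: i for i, t in enumerate(times)}
    m_index = {m: j for j, m in enumerate(mzs)}
    intensities = np.zeros((times.size, mzs.size))
    for t, m, v in df.itertuples(index=False):
        intensities[t_index[t], m_index[m]] += v
    return tis.GcmsRun(times, mzs, intensities, sample_id=sample_id)


# --------------------------------------------------------------------------
# minimal mzML writer + pyteomics-backed reader
# --------------------------------------------------------------------------
_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64_floats(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *np.asarray(values, dtype=float))
    return base64.b64encode(zlib.compress(raw)).decode()


def write_run_mzml(run: tis.GcmsRun, path: str | Path) -> None:
    """Write the run as centroided unit-mass mzML (64-bit, zlib arrays)."""
    E = lambda tag, **attrs: etree.SubElement(parent_stack[-1], f"{{{_MZML_NS}}}{tag}", **attrs)  # noqa: E731
    root = etree.Element(f"{{{_MZML_NS}}}mzML", version="1.1.0")
    parent_stack = [root]

    def push(el):
        parent_stack.append(el)

    def pop():
        parent_stack.pop()

    def cv_param(accession, name, value=None, unit=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name}
        if value is not None:
            attrs["value"] = str(value)
        if unit is not None:
            attrs.update(
                {"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]}
            )
        etree.SubElement(parent_stack[-1], f"{{{_MZML_NS}}}cvParam", **attrs)

    cv_list = E("cvList", count="2")
    push(cv_list)
    E("cv", id="MS", fullName="PSI-MS", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    E("cv", id="UO", fullName="UNIT-ONTOLOGY", URI="http://ontologies.berkeleybop.org/uo.obo")
    pop()
    run_el = E("run", id=run.sample_id or "run")
    push(run_el)
    spec_list = E("spectrumList", count=str(run.scan_times.size))
    push(spec_list)
    for s, t in enumerate(run.scan_times):
        row = run.intensities[s]
        nz = np.nonzero(row)[0]
        spec = E(
            "spectrum", index=str(s), id=f"scan={s + 1}",
            defaultArrayLength=str(nz.size),
        )
        push(spec)
        cv_param("MS:1000511", "ms level", 1)
        cv_param("MS:1000127", "centroid spectrum")
        scan_list = E("scanList", count="1")
        push(scan_list)
        scan = E("scan")
        push(scan)
        cv_param("MS:1000016", "scan start time", f"{t:.6f}", unit=("UO:0000031", "minute"))
        pop()
        pop()
        bda_list = E("binaryDataArrayList", count="2")
        push(bda_list)
        for accession, name, values in (
            ("MS:1000514", "m/z array", run.mz_axis[nz].astype(float)),
            ("MS:1000515", "intensity array", row[nz]),
        ):
            payload = _b64_floats(values)
            bda = E("binaryDataArray", encodedLength=str(len(payload)))
            push(bda)
            cv_param("MS:1000523", "64-bit float")
            cv_param("MS:1000574", "zlib compression")
            cv_param(accession, name)
            binary = etree.SubElement(parent_stack[-1], f"{{{_MZML_NS}}}binary")
            binary.text = payload
            pop()
        pop()
        pop()
    pop()
    pop()
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def _decode_binary(bda_el) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, optional zlib)."""
    accessions = {
        el.get("accession") for el in bda_el.findall(f"{{{_MZML_NS}}}cvParam")
    }
    text = bda_el.findtext(f"{{{_MZML_NS}}}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_run_mzml(path: str | Path, sample_id: str | None = None) -> tis.GcmsRun:
    """Read an mzML file into a run, binning m/z to nearest integer.

    A small direct parser (namespace-aware lxml walk over ``spectrum``
    elements with standard PSI-MS accessions) covering centroided MS1 data.
    """
    times, spectra = [], []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: not parseable as mzML ({exc})") from exc
    for spec in tree.iter(f"{{{_MZML_NS}}}spectrum"):
        scan_time = None
        for cv in spec.iter(f"{{{_MZML_NS}}}cvParam"):
            if cv.get("accession") == "MS:1000016":
                scan_time = float(cv.get("value"))
        arrays = {}
        for bda in spec.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            accs = {el.get("accession") for el in bda.findall(f"{{{_MZML_NS}}}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary(bda)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary(bda)
        if scan_time is None or "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(
                f"{path}: spectrum {spec.get('id')!r} lacks scan time or arrays"
            )
        times.append(scan_time)
        spectra.append((arrays["mz"], arrays["intensity"]))
    if not spectra:
        raise ValueError(f"{path}: no spectra found")
    all_mz = np.unique(
        np.concatenate([np.rint(mz).astype(int) for mz, _ in spectra])
    )
    lut = {m: j for j, m in enumerate(all_mz)}
    intensities = np.zeros((len(spectra), all_mz.size))
    for s, (mz, inten) in enumerate(spectra):
        for m, v in zip(np.rint(mz).astype(int), inten):
            intensities[s, lut[m]] += v
    order = np.argsort(times)
    return tis.GcmsRun(
        np.asarray(times)[order], all_mz, intensities[order],
        sample_id=sample_id or Path(path).stem,
    )


def read_run(path: str | Path, format: str | None = None) -> tis.GcmsRun:
    """Dispatch on format (or file suffix): 'mzml' or 'csv'."""
    fmt = format or ("mzml" if str(path).lower().endswith(".mzml") else "csv")
    if fmt == "mzml":
        return read_run_mzml(path)
    if fmt == "csv":
        return read_run_csv(path)
    raise ValueError(f"unknown run format {fmt!r}")


def write_run(run: tis.GcmsRun, path: str | Path, format: str | None = None) -> None:
    fmt = format or ("mzml" if str(path).lower().endswith(".mzml") else "csv")
    if fmt == "mzml":
        write_run_mzml(run, path)
    elif fmt == "csv":
        write_run_csv(run, path)
    else:
        raise ValueError(f"unknown run format {fmt!r}")


# --------------------------------------------------------------------------
# pipeline configuration and orchestration
# --------------------------------------------------------------------------
class GeneratorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    noise_sd: float = 0.02
    lot_sd: float = 0.05
    peak_width: float = 3.0
    n_scans: int = 120


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    classifier: str = "svm"  # svm | rf
    regressor: str = "svr"  # svr | pls | rf
    grid_step: float = 0.5  # log2 grid step for SVM/SVR tuning
    grid_lo: float = -10.0
    grid_hi: float = 10.0
    ntree_final: int = 100


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "waxprint_out"
    mz_lo: int = 50
    mz_hi: int = 550
    generator: GeneratorConfig = GeneratorConfig()
    train: TrainConfig = TrainConfig()
    doe_responses_csv: str | None = None  # columns X1,X2,X3,response

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    names = ("simulate", "explore", "doe", "split", "tune", "train")
    return {n: int(s) for n, s in zip(names, rng.integers(0, 2**31 - 1, len(names)))}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> tis -> explore -> doe -> train and write a report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}, "artifacts": {}}

    def record(stage: str, files: list[Path]) -> None:
        report["stages"][stage] = {"seed": seeds.get(stage)}
        for f in files:
            report["artifacts"][f.name] = _sha256(f)

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        params = simulate.GeneratorParams(
            noise_sd=config.generator.noise_sd,
            lot_sd=config.generator.lot_sd,
            peak_width=config.generator.peak_width,
            n_scans=config.generator.n_scans,
            seed=seeds[stage],
        )
        runs, metadata = simulate.make_study(params, seed=seeds[stage])
        meta_path = out / "metadata.csv"
        metadata.to_csv(meta_path, index=False)
        record(stage, [meta_path])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- tis ---------------------------------------------------------------
    stage = "tis"
    try:
        spectra = []
        for run, row in zip(runs, metadata.itertuples(index=False)):
            t = tis.base_peak_normalize(
                tis.collapse_to_tis(run, config.mz_lo, config.mz_hi)
            )
            t.lot, t.blend_pct, t.replicate = row.lot, row.blend_pct, row.replicate
            spectra.append(t)
        matrix = tis.assemble_matrix(spectra)
        matrix_path = out / "tis_matrix.csv"
        tis.write_matrix_csv(matrix, matrix_path)
        record(stage, [matrix_path])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- explore -----------------------------------------------------------
    stage = "explore"
    try:
        best, coeffs = cluster.select_linkage(matrix)
        hca = cluster.run_hca(matrix, method=best)
        (out / "dendrogram.nwk").write_text(hca.newick())
        hca.merges_table().to_csv(out / "hca_merges.csv", index=False)
        pca = cluster.run_pca(matrix, n_components=2)
        pca.scores.to_csv(out / "pca_scores.csv")
        pca.loadings.to_csv(out / "pca_loadings.csv")
        report["stages"]["explore_summary"] = {
            "linkage": best,
            "agglomerative_coefficients": coeffs,
            "explained_variance_pct": (pca.explained_variance_fraction * 100).tolist(),
        }
        record(stage, [out / "dendrogram.nwk", out / "hca_merges.csv",
                       out / "pca_scores.csv", out / "pca_loadings.csv"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- doe ---------------------------------------------------------------
    stage = "doe"
    try:
        if config.doe_responses_csv:
            df = pd.read_csv(config.doe_responses_csv)
            study = load_headspace_bbd().with_responses(df["response"].to_numpy())
            study.design.loc[:, ["X1", "X2", "X3"]] = df[["X1", "X2", "X3"]].to_numpy()
        else:
            study = load_headspace_bbd()
        results = ResponseSurfaceModel(study).fit()
        opt = results.optimize(seed=seeds[stage])
        grid_pt, grid_val = grid_scan(results.predict)
        f_lof, p_lof = results.lack_of_fit()
        doe_report = {
            "coefficients": {k: float(v) for k, v in results.params.items()},
            "r_squared_pct": results.rsquared * 100,
            "lack_of_fit": {"f": f_lof, "p": p_lof},
            "anova": results.anova().reset_index().to_dict(orient="records"),
            "optimum_coded": opt.coded.tolist(),
            "optimum_natural": opt.natural,
            "optimum_predicted": opt.predicted,
            "grid_check": {"point": grid_pt.tolist(), "value": grid_val},
        }
        (out / "doe_report.json").write_text(json.dumps(doe_report, indent=2))
        report["stages"]["doe_summary"] = doe_report
        record(stage, [out / "doe_report.json"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- train -------------------------------------------------------------
    stage = "train"
    try:
        grades = metadata["grade"].to_numpy()
        blends = metadata["blend_pct"].to_numpy(dtype=float)
        spec = learn.SplitSpec(seed=seeds["split"])
        Xtr, Xte, ytr, yte = learn.split_data(matrix, grades, spec)
        grid = tuple(
            np.arange(config.train.grid_lo, config.train.grid_hi + 1e-9,
                      config.train.grid_step)
        )
        svm_cfg = learn.SvmConfig(log2_C_grid=grid, log2_sigma_grid=grid)
        summary = {}
        if config.train.classifier == "svm":
            C, sigma, _ = learn.tune_svm(Xtr, ytr, svm_cfg, "classify", seeds["tune"])
            clf = learn.train_svm(Xtr, ytr, C, sigma, seed=seeds["train"],
                                  feature_names=list(Xtr.columns))
        else:
            clf = learn.rf_fit(Xtr, ytr, learn.RfConfig(ntree_final=config.train.ntree_final),
                               "classify", seed=seeds["train"])
        clf.evaluate(Xte, yte)
        summary["classifier"] = {
            "algorithm": clf.algorithm,
            "hyperparameters": {k: v for k, v in clf.hyperparameters.items()},
            "cv_metrics": {k: v for k, v in clf.cv_metrics.items() if np.isscalar(v)},
            "test_metrics": clf.test_metrics,
        }
        Xtr_r, Xte_r, ytr_r, yte_r = learn.split_data(matrix, blends, spec)
        if config.train.regressor == "svr":
            C, sigma, _ = learn.tune_svm(Xtr_r, ytr_r, svm_cfg, "regress", seeds["tune"])
            reg = learn.train_svr(Xtr_r, ytr_r, C, sigma, seed=seeds["train"],
                                  feature_names=list(Xtr_r.columns))
        elif config.train.regressor == "pls":
            reg = learn.pls_fit(Xtr_r, ytr_r, seed=seeds["train"])
        else:
            reg = learn.rf_fit(Xtr_r, ytr_r, learn.RfConfig(ntree_final=config.train.ntree_final),
                               "regress", seed=seeds["train"])
        reg.evaluate(Xte_r, yte_r)
        summary["regressor"] = {
            "algorithm": reg.algorithm,
            "hyperparameters": {k: v for k, v in reg.hyperparameters.items()
                                if np.isscalar(v)},
            "cv_metrics": {k: v for k, v in reg.cv_metrics.items() if np.isscalar(v)},
            "test_metrics": reg.test_metrics,
        }
        (out / "model_report.json").write_text(json.dumps(summary, indent=2))
        report["stages"]["train_summary"] = summary
        record(stage, [out / "model_report.json"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    report_path = out / "pipeline_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    return report
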