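"""File formats: the dosage CSV dialect, truth sidecars, phased maps,
pairwise-matrix export, dataset filtering and segregation QC.

Dosage file dialect: comma-separated, ``#`` comment lines, three header
records (``ploidy``, ``n.mrk``, ``n.ind``), then a table with columns
``marker,dP,dQ,<individual...>``.  Missing observations are ``NA``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from . import __version__
from .model import feasible_dosage_classes, polysomic_prior
from .states import _check_ploidy

__all__ = ["DosageDataset", "read_dosage_file", "write_dosage_file",
           "filter_impossible_dosages", "segregation_check", "build_priors",
           "write_truth", "read_truth", "write_phased_map", "read_phased_map",
           "write_pairwise", "read_vcf_dosages"]

MISSING = "NA"


class ParseError(ValueError):
    """Malformed dosage file; message carries the offending line number."""


@dataclass
class DosageDataset:
    """A marker dosage matrix for one full-sib family."""

    m: int
    markers: pd.DataFrame  # columns: name, dP, dQ
    dosages: np.ndarray  # (z, n), float with NaN for missing
    individuals: list[str]
    priors: np.ndarray | None = None  # (z, n, m+1) caller posteriors

    def __post_init__(self):
        _check_ploidy(self.m)
        z, n = self.dosages.shape
        if len(self.markers) != z or len(self.individuals) != n:
            raise ValueError("marker table / individual list inconsistent with matrix shape")
        for col in ("dP", "dQ"):
            bad = ~self.markers[col].between(0, self.m)
            if bad.any():
                raise ValueError(f"{col} out of range 0..{self.m} for markers "
                                 f"{self.markers.loc[bad, 'name'].tolist()}")
        with np.errstate(invalid="ignore"):
            out = (self.dosages < 0) | (self.dosages > self.m)
        if np.nansum(out):
            k, i = np.argwhere(out)[0]
            raise ValueError(
                f"dosage out of range at marker {self.markers['name'].iloc[k]!r}, "
                f"individual {self.individuals[i]!r}: {self.dosages[k, i]}"
            )

    @property
    def z(self) -> int:
        return self.dosages.shape[0]

    @property
    def n(self) -> int:
        return self.dosages.shape[1]

    @property
    def dP(self) -> np.ndarray:
        return self.markers["dP"].to_numpy()

    @property
    def dQ(self) -> np.ndarray:
        return self.markers["dQ"].to_numpy()


def _header_lines(params: dict) -> list[str]:
    lines = [f"# polylink v{__version__}"]
    for key, val in params.items():
        lines.append(f"# {key}: {val}")
    return lines


def write_dosage_file(dataset: DosageDataset, path, params: dict | None = None) -> None:
    with open(path, "w", newline="") as fh:
        for line in _header_lines(params or {}):
            fh.write(line + "\n")
        fh.write(f"ploidy,{dataset.m}\n")
        fh.write(f"n.mrk,{dataset.z}\n")
        fh.write(f"n.ind,{dataset.n}\n")
        writer = csv.writer(fh)
        writer.writerow(["marker", "dP", "dQ", *dataset.individuals])
        for k in range(dataset.z):
            row = dataset.markers.iloc[k]
            obs = [MISSING if np.isnan(v) else str(int(v)) for v in dataset.dosages[k]]
            writer.writerow([row["name"], int(row["dP"]), int(row["dQ"]), *obs])


def read_dosage_file(path) -> DosageDataset:
    """Parse and validate a dosage file; malformed content raises
    :class:`ParseError` with the line number."""
    meta: dict[str, int] = {}
    names, dP, dQ, rows = [], [], [], []
    individuals: list[str] | None = None
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = next(csv.reader([line]))
            if individuals is None:
                key = cells[0].lower()
                if key in ("ploidy", "n.mrk", "n.ind"):
                    try:
                        meta[key] = int(cells[1])
                    except (IndexError, ValueError):
                        raise ParseError(f"line {lineno}: bad header record {line!r}")
                    continue
                if key != "marker":
                    raise ParseError(f"line {lineno}: expected header keys or column row, got {line!r}")
                if "ploidy" not in meta:
                    raise ParseError(f"line {lineno}: 'ploidy' header missing before the table")
                individuals = cells[3:]
                if len(individuals) != meta.get("n.ind", len(individuals)):
                    raise ParseError(
                        f"line {lineno}: {len(individuals)} individual columns but "
                        f"n.ind={meta['n.ind']}"
                    )
                continue
            if len(cells) != 3 + len(individuals):
                raise ParseError(
                    f"line {lineno}: expected {3 + len(individuals)} fields, got {len(cells)}"
                )
            name = cells[0]
            if name in names:
                raise ParseError(f"line {lineno}: duplicated marker name {name!r}")
            try:
                dp, dq = int(cells[1]), int(cells[2])
            except ValueError:
                raise ParseError(f"line {lineno}: parental dosages must be integers")
            obs = []
            for col, cell in enumerate(cells[3:]):
                if cell == MISSING or cell == "":
                    obs.append(np.nan)
                    continue
                try:
                    val = int(cell)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: bad dosage {cell!r} for marker {name!r}, "
                        f"individual {individuals[col]!r}"
                    )
                if not 0 <= val <= meta["ploidy"]:
                    raise ParseError(
                        f"line {lineno}: dosage {val} out of range 0..{meta['ploidy']} "
                        f"for marker {name!r}, individual {individuals[col]!r}"
                    )
                obs.append(float(val))
            names.append(name)
            dP.append(dp)
            dQ.append(dq)
            rows.append(obs)
    if individuals is None or not rows:
        raise ParseError("no marker table found")
    if "n.mrk" in meta and meta["n.mrk"] != len(rows):
        raise ParseError(f"n.mrk={meta['n.mrk']} but {len(rows)} marker rows found")
    markers = pd.DataFrame({"name": names, "dP": dP, "dQ": dQ})
    return DosageDataset(m=meta["ploidy"], markers=markers,
                         dosages=np.array(rows, dtype=float), individuals=individuals)


def filter_impossible_dosages(dataset: DosageDataset) -> tuple[DosageDataset, pd.DataFrame]:
    """Set observations outside the polysomic-feasible dosage classes for
    the marker's parental dosages to missing; report counts per marker."""
    dosages = dataset.dosages.copy()
    counts = np.zeros(dataset.z, dtype=int)
    for k in range(dataset.z):
        feas = feasible_dosage_classes(int(dataset.dP[k]), int(dataset.dQ[k]), dataset.m)
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(dosages[k]) & ~np.isin(dosages[k], sorted(feas))
        counts[k] = bad.sum()
        dosages[k, bad] = np.nan
    report = pd.DataFrame({"name": dataset.markers["name"], "n_filtered": counts})
    out = DosageDataset(m=dataset.m, markers=dataset.markers.copy(), dosages=dosages,
                        individuals=list(dataset.individuals), priors=dataset.priors)
    return out, report


def segregation_check(dataset: DosageDataset) -> pd.DataFrame:
    """Chi-square goodness of fit of the observed offspring dosage
    frequencies against the polysomic expectation, per marker."""
    stats, pvals, nobs = [], [], []
    for k in range(dataset.z):
        expected = polysomic_prior(int(dataset.dP[k]), int(dataset.dQ[k]), dataset.m)
        obs = dataset.dosages[k]
        obs = obs[~np.isnan(obs)].astype(int)
        support = np.where(expected > 0)[0]
        if obs.size == 0 or support.size < 2:
            stats.append(0.0)
            pvals.append(1.0)
            nobs.append(obs.size)
            continue
        counts = np.bincount(obs, minlength=dataset.m + 1)[support]
        stat, p = chisquare(counts, f_exp=expected[support] * obs.size)
        stats.append(float(stat))
        pvals.append(float(p))
        nobs.append(obs.size)
    return pd.DataFrame({"name": dataset.markers["name"], "n": nobs,
                         "chi2": stats, "pvalue": pvals})


def build_priors(dataset: DosageDataset, error_rate: float = 0.0) -> np.ndarray:
    """Per-individual priors (n, z, m+1) for estimation: caller posteriors
    when present, else hard calls with an optional global error rate;
    missing values get the polysomic prior."""
    from .sim import indicator_priors

    if dataset.priors is not None:
        return np.transpose(dataset.priors, (1, 0, 2)).copy()
    return indicator_priors(dataset.dosages, dataset.dP, dataset.dQ, dataset.m,
                            error_rate=error_rate)


# -- truth sidecar -----------------------------------------------------------

def write_truth(truth, path, m: int) -> None:
    payload = {
        "version": __version__,
        "m": m,
        "HP": np.asarray(truth.HP).tolist(),
        "HQ": np.asarray(truth.HQ).tolist(),
        "tracks_P": np.asarray(truth.tracks_P).tolist(),
        "tracks_Q": np.asarray(truth.tracks_Q).tolist(),
        "dosages": np.asarray(truth.dosages).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path):
    from .sim import TruthRecord

    with open(path) as fh:
        payload = json.load(fh)
    return payload["m"], TruthRecord(
        HP=np.array(payload["HP"], dtype=np.int8),
        HQ=np.array(payload["HQ"], dtype=np.int8),
        tracks_P=np.array(payload["tracks_P"]),
        tracks_Q=np.array(payload["tracks_Q"]),
        dosages=np.array(payload["dosages"], dtype=float),
    )


# -- phased map --------------------------------------------------------------

def write_phased_map(path, marker_names, dP, dQ, HP, HQ, r, loglik: float,
                     m: int, params: dict | None = None) -> None:
    """Delimited phased-map export: marker, cumulative Haldane position,
    parental dosages, per-homolog allele indicators, r to the next marker."""
    from .sim import haldane

    z = len(marker_names)
    r = np.asarray(r, dtype=float)
    pos = np.concatenate([[0.0], np.cumsum(haldane(np.minimum(r, 0.49999)))])
    with open(path, "w") as fh:
        for line in _header_lines({**(params or {}), "ploidy": m, "loglik": f"{loglik:.6f}"}):
            fh.write(line + "\n")
        cols = (["marker", "pos_cM", "dP", "dQ"]
                + [f"P{i}" for i in range(1, m + 1)]
                + [f"Q{i}" for i in range(1, m + 1)] + ["r_next"])
        fh.write("\t".join(cols) + "\n")
        for k in range(z):
            r_next = f"{r[k]:.8f}" if k < z - 1 else MISSING
            cells = ([str(marker_names[k]), f"{pos[k]:.4f}", str(int(dP[k])), str(int(dQ[k]))]
                     + [str(int(HP[i, k])) for i in range(m)]
                     + [str(int(HQ[i, k])) for i in range(m)] + [r_next])
            fh.write("\t".join(cells) + "\n")


def read_phased_map(path):
    df = pd.read_csv(path, sep="\t", comment="#")
    pcols = [c for c in df.columns if c.startswith("P") and c[1:].isdigit()]
    qcols = [c for c in df.columns if c.startswith("Q") and c[1:].isdigit()]
    m = len(pcols)
    HP = df[pcols].to_numpy().T
    HQ = df[qcols].to_numpy().T
    r = pd.to_numeric(df["r_next"], errors="coerce").to_numpy()[:-1]
    return {"markers": df["marker"].tolist(), "dP": df["dP"].to_numpy(),
            "dQ": df["dQ"].to_numpy(), "HP": HP, "HQ": HQ, "r": r, "m": m}


def write_pairwise(table: pd.DataFrame, path, marker_names, params: dict | None = None) -> None:
    out = table.copy()
    out["marker1"] = [marker_names[i] for i in out["marker1"]]
    out["marker2"] = [marker_names[i] for i in out["marker2"]]
    with open(path, "w") as fh:
        for line in _header_lines(params or {}):
            fh.write(line + "\n")
        out.to_csv(fh, sep="\t", index=False)


# -- VCF convenience reader --------------------------------------------------

def read_vcf_dosages(path, parent_p: str, parent_q: str, m: int) -> DosageDataset:
    """Extract a dosage dataset from a VCF: uses the DS format field
    (rounded) when present, else counts ALT alleles in GT.  The two parent
    samples become dP/dQ; everything else is treated as offspring."""
    from cyvcf2 import VCF

    m = _check_ploidy(m)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for parent in (parent_p, parent_q):
        if parent not in samples:
            raise ValueError(f"parent sample {parent!r} not found in VCF")
    ip, iq = samples.index(parent_p), samples.index(parent_q)
    offspring_idx = [i for i in range(len(samples)) if i not in (ip, iq)]
    names, dP, dQ, rows = [], [], [], []
    for var in vcf:
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), dtype=float).reshape(len(samples), -1)[:, 0]
            calls = np.where(np.isnan(ds), np.nan, np.round(ds))
        else:
            gts = var.genotype.array()
            alleles = gts[:, :-1]
            missing = (alleles < 0).any(axis=1)
            calls = np.where(missing, np.nan, (alleles > 0).sum(axis=1).astype(float))
        if np.isnan(calls[ip]) or np.isnan(calls[iq]):
            continue
        names.append(var.ID or f"{var.CHROM}_{var.POS}")
        dP.append(int(calls[ip]))
        dQ.append(int(calls[iq]))
        rows.append([calls[i] for i in offspring_idx])
    markers = pd.DataFrame({"name": names, "dP": dP, "dQ": dQ})
    return DosageDataset(m=m, markers=markers, dosages=np.array(rows, dtype=float),
                         individuals=[samples[i] for i in offspring_idx])
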