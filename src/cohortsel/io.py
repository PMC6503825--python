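"""Readers, writers and fixture generation for the tabular interchange formats.

The contract format is a counts TSV with one row per locus per time step and
columns ``locus_id, time_index, y11, y12, y22`` (tab-separated, UTF-8, header
required).  Per-individual genotype tables (rows = individuals, one column per
locus, codes 0/1/2 = copies of allele 1, empty or ``NA`` = missing) are
converted to counts at this boundary using a sample-to-time map.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeCounts, TemporalLocusData
from .neutrality import ScanOutput
from .simulate import SimulationScenario, simulate_cohort_study

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_individuals_table",
    "scan_to_frame",
    "write_scan_tsv",
    "generate_fixture",
]

COUNT_COLUMNS = ["locus_id", "time_index", "y11", "y12", "y22"]

FIXTURE_KINDS = ("neutral_small", "strong_selection", "empirical_shape")


def read_counts_tsv(path: str | Path) -> list[TemporalLocusData]:
    """Parse a counts TSV into per-locus temporal series.

    Raises ``ValueError`` itemizing missing columns, duplicate (locus, time)
    rows, negative or non-integer counts, and non-contiguous time indices.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dups = df.duplicated(subset=["locus_id", "time_index"], keep=False)
    if dups.any():
        bad = df.loc[dups, ["locus_id", "time_index"]].drop_duplicates()
        pairs = ", ".join(f"({r.locus_id}, t={r.time_index})" for r in bad.itertuples())
        raise ValueError(f"{path}: duplicate (locus, time) rows: {pairs}")

    problems: list[str] = []
    out: list[TemporalLocusData] = []
    for locus_id, grp in df.groupby("locus_id", sort=True):
        grp = grp.sort_values("time_index")
        times = grp["time_index"].to_numpy()
        if not np.array_equal(times, np.arange(len(times))):
            problems.append(f"locus {locus_id}: time indices must be contiguous from 0, got {list(times)}")
            continue
        try:
            samples = tuple(
                GenotypeCounts(int(r.y11), int(r.y12), int(r.y22))
                if float(r.y11).is_integer() and float(r.y12).is_integer() and float(r.y22).is_integer()
                and r.y11 >= 0 and r.y12 >= 0 and r.y22 >= 0
                else (_ for _ in ()).throw(ValueError("negative or non-integer count"))
                for r in grp.itertuples()
            )
            out.append(TemporalLocusData(locus_id=str(locus_id), samples=samples))
        except (ValueError, TypeError) as exc:
            problems.append(f"locus {locus_id}: {exc}")
    if problems:
        raise ValueError(f"{path}: malformed rows:\n  " + "\n  ".join(problems))
    return out


def write_counts_tsv(data: Sequence[TemporalLocusData], path: str | Path) -> None:
    """Write a dataset back to the counts TSV schema (lossless round-trip)."""
    rows = [
        {"locus_id": locus.locus_id, "time_index": t, "y11": c.y11, "y12": c.y12, "y22": c.y22}
        for locus in data
        for t, c in enumerate(locus.samples)
    ]
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_individuals_table(
    path: str | Path,
    time_map: Mapping[str, int] | str | Path,
) -> list[TemporalLocusData]:
    """Convert a per-individual genotype matrix to per-locus temporal counts.

    The table's first column is the individual id; every other column is a
    locus with genotype codes 0/1/2 (copies of allele 1) or missing (empty or
    ``NA``).  ``time_map`` maps each individual to its time step, either as a
    mapping or a two-column TSV (``individual_id, time_index``).  Missing
    genotypes are dropped per locus, so sample sizes may differ across loci.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.empty or df.shape[1] < 2:
        import warnings

        warnings.warn(f"{path}: empty individual table", UserWarning)
        return []
    if not isinstance(time_map, Mapping):
        tm = pd.read_csv(time_map, sep="\t", dtype={0: str})
        time_map = dict(zip(tm.iloc[:, 0], tm.iloc[:, 1].astype(int)))
    id_col = df.columns[0]
    loci = list(df.columns[1:])

    unmapped = [i for i in df[id_col] if i not in time_map]
    if unmapped:
        raise ValueError(f"{path}: individuals without a time assignment: {unmapped}")
    times = df[id_col].map(time_map).to_numpy()
    n_steps = int(times.max()) + 1

    out: list[TemporalLocusData] = []
    for locus in loci:
        codes = pd.to_numeric(df[locus], errors="coerce").to_numpy(dtype=float)
        samples = []
        for t in range(n_steps):
            at_t = codes[times == t]
            at_t = at_t[~np.isnan(at_t)]
            if not np.isin(at_t, [0, 1, 2]).all():
                bad = sorted(set(at_t) - {0, 1, 2})
                raise ValueError(f"{path}: locus {locus}: invalid genotype code(s) {bad}")
            samples.append(
                GenotypeCounts(
                    int((at_t == 2).sum()), int((at_t == 1).sum()), int((at_t == 0).sum())
                )
            )
        out.append(TemporalLocusData(locus_id=str(locus), samples=tuple(samples)))
    return out


def scan_to_frame(output: ScanOutput) -> pd.DataFrame:
    """Tidy table of scan results (one row per locus per period)."""
    return pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "period": r.period,
                "delta_obs": r.delta_obs,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in output.results
        ]
    )


def write_scan_tsv(
    output: ScanOutput,
    path: str | Path,
    data: Sequence[TemporalLocusData] | None = None,
) -> None:
    """Write scan results as TSV; with ``data`` given, adds sample sizes and MAF."""
    df = scan_to_frame(output)
    if data is not None and len(df):
        by_id = {d.locus_id: d for d in data}
        df["n_prev"] = [by_id[r.locus_id].samples[r.period - 1].n for r in output.results]
        df["n_curr"] = [by_id[r.locus_id].samples[r.period].n for r in output.results]
        df["maf_pooled"] = [by_id[r.locus_id].pooled_maf() for r in output.results]
        df = df[
            ["locus_id", "period", "n_prev", "n_curr", "maf_pooled",
             "delta_obs", "p_value", "q_value", "significant"]
        ]
    df.to_csv(path, sep="\t", index=False)


def _fixture_loci(
    rng: np.random.Generator,
    n_loci: int,
    sample_sizes: tuple[int, ...],
    s: tuple[float, ...],
    N: int = 10_000,
    maf_range: tuple[float, float] = (0.08, 0.5),
) -> list[TemporalLocusData]:
    loci = []
    for i in range(n_loci):
        maf = float(rng.uniform(*maf_range))
        sc = SimulationScenario(
            N=N, sample_sizes=sample_sizes, maf=maf, s=s, h=0.5, replicates=1
        )
        loci.append(simulate_cohort_study(sc, rng=rng, locus_id=f"L{i:04d}"))
    return loci


def generate_fixture(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write a deterministic counts-TSV fixture of a named kind.

    ``neutral_small``: 10 neutral loci, two time steps of 100.
    ``strong_selection``: 20 neutral loci plus 5 with s = -0.1, with a
    ``*_truth.tsv`` sidecar listing the true s per locus.
    ``empirical_shape``: a neutral dataset shaped like a seedling cohort
    field study — three time steps of sizes 101/109/45 and 237 loci.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    if kind == "neutral_small":
        loci = _fixture_loci(rng, 10, (100, 100), (0.0,))
        path = out_dir / "neutral_small.tsv"
        write_counts_tsv(loci, path)
        written.append(path)
    elif kind == "strong_selection":
        # selected loci sit at intermediate MAF, where the test has power
        neutral = _fixture_loci(rng, 20, (1000, 1000), (0.0,))
        selected = _fixture_loci(rng, 5, (1000, 1000), (-0.1,), maf_range=(0.3, 0.5))
        selected = [
            TemporalLocusData(locus_id=f"S{i:04d}", samples=d.samples)
            for i, d in enumerate(selected)
        ]
        loci = neutral + selected
        path = out_dir / "strong_selection.tsv"
        write_counts_tsv(loci, path)
        truth = out_dir / "strong_selection_truth.tsv"
        pd.DataFrame(
            {"locus_id": [d.locus_id for d in loci],
             "true_s": [0.0] * len(neutral) + [-0.1] * len(selected)}
        ).to_csv(truth, sep="\t", index=False)
        written += [path, truth]
    else:  # empirical_shape
        loci = _fixture_loci(rng, 237, (101, 109, 45), (0.0, 0.0), N=100_000)
        path = out_dir / "empirical_shape.tsv"
        write_counts_tsv(loci, path)
        written.append(path)
    return written
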