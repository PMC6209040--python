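"""Readers and writers for the tool's file formats.

Formats: sparky-style 3D peak lists, NMR-STAR 3.1 atom-chem-shift loops (and
an equivalent TSV dialect) for assigned tables, TSV for carbon-pair datasets,
corpora, model parameters, overlap priors and residual curves, FASTA or plain
text for sequences, plain H/E/C strings for secondary structure, JSON for
reports.  All TSV uses tab separation with '.' decimals; writers and readers
round-trip bit-exactly on their own output.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .classes import ONE_TO_THREE, THREE_TO_ONE, ClassKey, ALL_MODEL_KEYS
from .errors import FormatError, PeakListParseError, ValidationError
from .overlap import OverlapPrior
from .types import (
    AssignedRow,
    AssignedShiftTable,
    BivariateClassModel,
    CarbonPair,
    CarbonPairDataset,
    CorrectionResult,
    EntryQuality,
    ModelSet,
    Peak3D,
    ShiftRecord,
)

PathLike = Union[str, Path]

DIM_H, DIM_N, DIM_C = "H", "N", "C"
DEFAULT_DIM_ORDER = (DIM_H, DIM_N, DIM_C)


def _is_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return not math.isnan(float(token)) if token.lower() != "nan" else True


def read_peak_list(
    path: PathLike, dim_order: Sequence[str] = DEFAULT_DIM_ORDER
) -> list[Peak3D]:
    """Parse a sparky-style peak list into Peak3D records.

    Comment (#) and header lines are skipped.  Each data line is an optional
    assignment label, three shift columns in ``dim_order`` and an optional
    intensity.  A line with a non-numeric shift raises
    :class:`PeakListParseError` naming the line.
    """
    if sorted(dim_order) != sorted(DEFAULT_DIM_ORDER):
        raise ValidationError(f"dim_order must be a permutation of H,N,C: {dim_order}")
    peaks: list[Peak3D] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            numeric = [_is_float(t) for t in tokens]
            if not any(numeric):
                continue  # header line ("Assignment w1 w2 w3", ...)
            if not numeric[0]:
                tokens = tokens[1:]
                numeric = numeric[1:]
            if len(tokens) < 3 or not all(numeric[:3]):
                raise PeakListParseError(
                    f"{path}:{lineno}: expected three numeric shift columns, "
                    f"got {stripped!r}"
                )
            shifts = dict(zip(dim_order, (float(t) for t in tokens[:3])))
            intensity = None
            if len(tokens) > 3 and numeric[3]:
                intensity = float(tokens[3])
            peaks.append(
                Peak3D(
                    h_shift=shifts[DIM_H],
                    n_shift=shifts[DIM_N],
                    c_shift=shifts[DIM_C],
                    intensity=intensity,
                    line_index=lineno,
                )
            )
    if not peaks:
        raise FormatError(f"{path}: no data lines found")
    return peaks


def write_peak_list(peaks: Sequence[Peak3D], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# h_shift\tn_shift\tc_shift\tintensity\n")
        for p in peaks:
            inten = "" if p.intensity is None else f"{p.intensity:.6g}"
            fh.write(f"{p.h_shift:.4f}\t{p.n_shift:.3f}\t{p.c_shift:.3f}\t{inten}\n".rstrip() + "\n")


def read_sequence(path: PathLike) -> str:
    """Protein sequence from FASTA or a plain one-letter string file."""
    text = Path(path).read_text().strip()
    if text.startswith(">"):
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise FormatError(f"{path}: empty FASTA file")
        return str(records[0].seq).upper()
    return "".join(text.split()).upper()


def read_ss_string(path_or_string: PathLike) -> str:
    """Secondary-structure string; files and inline strings both accepted.

    Predictor letters are mapped H->H, E->E, everything else->C.
    """
    s = str(path_or_string)
    if Path(s).exists():
        s = Path(s).read_text()
    s = "".join(s.split()).upper()
    return "".join(c if c in "HE" else "C" for c in s)


# --- assigned tables: NMR-STAR 3.1 chemical-shift loop + TSV dialect -------

_STAR_TAGS = (
    "_Atom_chem_shift.ID",
    "_Atom_chem_shift.Comp_index_ID",
    "_Atom_chem_shift.Comp_ID",
    "_Atom_chem_shift.Atom_ID",
    "_Atom_chem_shift.Val",
)


def _parse_star_loop(path: PathLike) -> list[tuple[int, str, str, float]]:
    """(residue_index, residue_3letter, atom, value) rows of the shift loop."""
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() == "loop_":
            tags = []
            j = i + 1
            while j < len(lines) and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                rows = []
                while j < len(lines) and lines[j].strip() not in ("stop_",):
                    tokens = lines[j].split()
                    if tokens:
                        rows.append(tokens)
                    j += 1
                try:
                    idx = {
                        name: tags.index(tag)
                        for name, tag in (
                            ("seq", "_Atom_chem_shift.Comp_index_ID"),
                            ("comp", "_Atom_chem_shift.Comp_ID"),
                            ("atom", "_Atom_chem_shift.Atom_ID"),
                            ("val", "_Atom_chem_shift.Val"),
                        )
                    }
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: atom-chem-shift loop lacks a required tag"
                    ) from exc
                out = []
                for tokens in rows:
                    if len(tokens) < len(tags):
                        raise FormatError(f"{path}: short row in shift loop: {tokens}")
                    out.append(
                        (
                            int(tokens[idx["seq"]]),
                            tokens[idx["comp"]].upper(),
                            tokens[idx["atom"]].upper(),
                            float(tokens[idx["val"]]),
                        )
                    )
                return out
            i = j
        else:
            i += 1
    raise FormatError(f"{path}: no atom-chem-shift loop found")


def read_assigned_table(
    path: PathLike, ss_string: Optional[str] = None
) -> AssignedShiftTable:
    """Assigned CA/CB shifts from NMR-STAR 3.1 or the TSV dialect.

    CA and CB rows are joined per residue; residues with neither shift are
    dropped.  Secondary structure is attached from ``ss_string`` by residue
    index (1-based NMR-STAR numbering); 'C' is assumed where none is given.
    """
    text_head = Path(path).read_text(errors="replace")[:4096]
    first_line = text_head.splitlines()[0] if text_head else ""
    if "residue_index" in first_line:
        return _read_assigned_tsv(path, ss_string)
    try:
        rows = _parse_star_loop(path)
    except FormatError:
        return _read_assigned_tsv(path, ss_string)
    per_residue: dict[int, dict] = {}
    for seq_id, comp, atom, val in rows:
        if atom not in ("CA", "CB"):
            continue
        if comp not in THREE_TO_ONE:
            raise FormatError(f"{path}: unknown residue {comp}")
        entry = per_residue.setdefault(
            seq_id, {"aa": THREE_TO_ONE[comp], "CA": None, "CB": None}
        )
        entry[atom] = val
    out_rows = []
    for seq_id in sorted(per_residue):
        e = per_residue[seq_id]
        if e["CA"] is None and e["CB"] is None:
            continue
        if ss_string is not None and 1 <= seq_id <= len(ss_string):
            ss = ss_string[seq_id - 1]
        else:
            ss = "C"
        out_rows.append(
            AssignedRow(
                residue_index=seq_id,
                amino_acid=e["aa"],
                secondary_structure=ss,
                ca_shift=e["CA"],
                cb_shift=e["CB"],
            )
        )
    return AssignedShiftTable(rows=out_rows)


def _read_assigned_tsv(
    path: PathLike, ss_string: Optional[str] = None
) -> AssignedShiftTable:
    df = pd.read_csv(path, sep="\t", dtype={"amino_acid": str})
    required = {"residue_index", "amino_acid", "ca_shift"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: assigned TSV needs columns {sorted(required)}, got "
            f"{list(df.columns)}"
        )
    rows = []
    for _, r in df.iterrows():
        idx = int(r["residue_index"])
        if "secondary_structure" in df.columns and isinstance(
            r["secondary_structure"], str
        ):
            ss = r["secondary_structure"]
        elif ss_string is not None and 1 <= idx <= len(ss_string):
            ss = ss_string[idx - 1]
        else:
            ss = "C"
        ca = None if pd.isna(r["ca_shift"]) else float(r["ca_shift"])
        cb = None
        if "cb_shift" in df.columns and not pd.isna(r.get("cb_shift")):
            cb = float(r["cb_shift"])
        if ca is None and cb is None:
            continue
        rows.append(
            AssignedRow(
                residue_index=idx,
                amino_acid=str(r["amino_acid"]),
                secondary_structure=ss,
                ca_shift=ca,
                cb_shift=cb,
            )
        )
    return AssignedShiftTable(rows=rows)


def write_assigned_star(table: AssignedShiftTable, path: PathLike) -> None:
    """Minimal NMR-STAR 3.1 file carrying one atom-chem-shift loop."""
    with open(path, "w") as fh:
        fh.write("data_shifts\n\nsave_assigned_chemical_shifts\n")
        fh.write("   loop_\n")
        for tag in _STAR_TAGS:
            fh.write(f"      {tag}\n")
        i = 1
        for r in sorted(table.rows, key=lambda r: r.residue_index):
            comp = ONE_TO_THREE[r.amino_acid]
            for atom, val in (("CA", r.ca_shift), ("CB", r.cb_shift)):
                if val is None:
                    continue
                fh.write(
                    f"      {i} {r.residue_index} {comp} {atom} {val:.4f}\n"
                )
                i += 1
        fh.write("   stop_\nsave_\n")


def write_assigned_tsv(table: AssignedShiftTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("residue_index\tamino_acid\tsecondary_structure\tca_shift\tcb_shift\n")
        for r in sorted(table.rows, key=lambda r: r.residue_index):
            ca = "" if r.ca_shift is None else f"{r.ca_shift:.4f}"
            cb = "" if r.cb_shift is None else f"{r.cb_shift:.4f}"
            fh.write(
                f"{r.residue_index}\t{r.amino_acid}\t{r.secondary_structure}\t{ca}\t{cb}\n"
            )


# --- carbon-pair datasets and corpora --------------------------------------

def read_pairs_tsv(path: PathLike, sequence: str, ss_string: str) -> CarbonPairDataset:
    df = pd.read_csv(path, sep="\t")
    if not {"shift_a", "shift_b"}.issubset(df.columns):
        raise FormatError(f"{path}: pairs TSV needs columns shift_a, shift_b")
    pairs = [
        CarbonPair(float(a), float(b))
        for a, b in zip(df["shift_a"], df["shift_b"])
    ]
    return CarbonPairDataset(pairs=pairs, sequence=sequence, ss_string=ss_string)


def write_pairs_tsv(dataset: CarbonPairDataset, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("shift_a\tshift_b\n")
        for p in dataset.pairs:
            fh.write(f"{p.shift_a:.4f}\t{p.shift_b:.4f}\n")


def read_corpus_tsv(path: PathLike) -> list[ShiftRecord]:
    """Corpus TSV: entry_id, residue_index, amino_acid, secondary_structure,
    ca_shift, cb_shift (empty allowed)."""
    df = pd.read_csv(path, sep="\t", dtype={"entry_id": str, "amino_acid": str})
    records = []
    for _, r in df.iterrows():
        cb = None if "cb_shift" not in df.columns or pd.isna(r.get("cb_shift")) else float(r["cb_shift"])
        records.append(
            ShiftRecord(
                entry_id=str(r["entry_id"]),
                residue_index=int(r["residue_index"]),
                amino_acid=str(r["amino_acid"]),
                secondary_structure=str(r["secondary_structure"]),
                ca_shift=float(r["ca_shift"]),
                cb_shift=cb,
            )
        )
    return records


def write_corpus_tsv(records: Sequence[ShiftRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("entry_id\tresidue_index\tamino_acid\tsecondary_structure\tca_shift\tcb_shift\n")
        for r in records:
            cb = "" if r.cb_shift is None else f"{r.cb_shift:.4f}"
            fh.write(
                f"{r.entry_id}\t{r.residue_index}\t{r.amino_acid}\t"
                f"{r.secondary_structure}\t{r.ca_shift:.4f}\t{cb}\n"
            )


def read_entry_qualities_tsv(path: PathLike) -> list[EntryQuality]:
    from .statistics import make_entry_quality

    df = pd.read_csv(path, sep="\t", dtype={"entry_id": str})
    return [
        make_entry_quality(str(r["entry_id"]), float(r["rmsd_ca"]), float(r["rmsd_cb"]))
        for _, r in df.iterrows()
    ]


def write_entry_qualities_tsv(qualities: Sequence[EntryQuality], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("entry_id\trmsd_ca\trmsd_cb\n")
        for q in qualities:
            fh.write(f"{q.entry_id}\t{q.rmsd_ca:.6f}\t{q.rmsd_cb:.6f}\n")


# --- model sets and priors --------------------------------------------------

def write_model_set(model_set: ModelSet, path: PathLike) -> None:
    """One row per class key: variant, key, mu, sd, cov, n."""
    with open(path, "w") as fh:
        fh.write("variant\tamino_acid_class\tsecondary_structure\tmu_ca\tmu_cb\tsd_ca\tsd_cb\tcov\tn\n")
        for key in ALL_MODEL_KEYS:
            m = model_set[key]
            cells = [
                model_set.variant,
                key.amino_acid_class,
                key.secondary_structure,
                f"{m.mu_ca:.6f}",
                "" if m.mu_cb is None else f"{m.mu_cb:.6f}",
                f"{m.sd_ca:.6f}",
                "" if m.sd_cb is None else f"{m.sd_cb:.6f}",
                "" if m.cov is None else f"{m.cov:.6f}",
                str(m.n),
            ]
            fh.write("\t".join(cells) + "\n")


def read_model_set(path: PathLike) -> ModelSet:
    df = pd.read_csv(path, sep="\t", dtype={"amino_acid_class": str})
    variant = str(df["variant"].iloc[0])
    models = {}
    for _, r in df.iterrows():
        key = ClassKey(str(r["amino_acid_class"]), str(r["secondary_structure"]))
        models[key] = BivariateClassModel(
            key=key,
            mu_ca=float(r["mu_ca"]),
            mu_cb=None if pd.isna(r["mu_cb"]) else float(r["mu_cb"]),
            sd_ca=float(r["sd_ca"]),
            sd_cb=None if pd.isna(r["sd_cb"]) else float(r["sd_cb"]),
            cov=None if pd.isna(r["cov"]) else float(r["cov"]),
            n=int(r["n"]),
        )
    return ModelSet(variant=variant, models=models)


def write_prior(prior: OverlapPrior, path: PathLike) -> None:
    df = pd.DataFrame(prior.omega, index=prior.labels, columns=prior.labels)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="class")


def read_prior(path: PathLike) -> OverlapPrior:
    import numpy as np

    df = pd.read_csv(path, sep="\t", index_col=0)
    omega = df.to_numpy(dtype=float)
    return OverlapPrior(
        omega=omega,
        weights=np.diag(omega).copy(),
        labels=tuple(df.columns),
    )


# --- outputs ----------------------------------------------------------------

def write_residual_curve(result: CorrectionResult, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_ppm\tresidual\n")
        for c, r in result.residual_curve:
            fh.write(f"{c:.6f}\t{r:.10g}\n")


def write_outputs(
    result: CorrectionResult,
    data: Union[Sequence[Peak3D], CarbonPairDataset, AssignedShiftTable],
    outdir: PathLike,
    config: Optional[dict] = None,
    plot: bool = False,
) -> dict[str, Path]:
    """Write the report JSON, corrected shifts and residual curve.

    The corrected output subtracts the final correction from every 13C shift
    (1H/15N untouched).  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    report = {
        "m1": result.m1,
        "m2": result.m2,
        "final_residual": result.final_residual,
        "method": result.method,
        "config": config or {},
    }
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    paths["residual_curve"] = outdir / "residual_curve.tsv"
    write_residual_curve(result, paths["residual_curve"])

    m2 = result.m2
    if isinstance(data, CarbonPairDataset):
        from .engine import apply_correction

        paths["corrected"] = outdir / "corrected_pairs.tsv"
        write_pairs_tsv(apply_correction(data, m2), paths["corrected"])
    elif isinstance(data, AssignedShiftTable):
        corrected = AssignedShiftTable(
            rows=[
                AssignedRow(
                    residue_index=r.residue_index,
                    amino_acid=r.amino_acid,
                    secondary_structure=r.secondary_structure,
                    ca_shift=None if r.ca_shift is None else r.ca_shift - m2,
                    cb_shift=None if r.cb_shift is None else r.cb_shift - m2,
                )
                for r in data.rows
            ]
        )
        paths["corrected"] = outdir / "corrected_shifts.str"
        write_assigned_star(corrected, paths["corrected"])
    else:
        corrected_peaks = [
            Peak3D(
                h_shift=p.h_shift,
                n_shift=p.n_shift,
                c_shift=p.c_shift - m2,
                intensity=p.intensity,
                line_index=p.line_index,
            )
            for p in data
        ]
        paths["corrected"] = outdir / "corrected_peaks.tsv"
        write_peak_list(corrected_peaks, paths["corrected"])

    if plot:
        paths["plot"] = outdir / "residual_curve.png"
        _plot_residual_curve(result, paths["plot"])
    return paths


def _plot_residual_curve(result: CorrectionResult, path: PathLike) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [c for c, _ in result.residual_curve]
    ys = [r for _, r in result.residual_curve]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(xs, ys, ".", ms=4)
    ax.axvline(result.m2, color="crimson", lw=1, label=f"correction = {result.m2:.3f} ppm")
    ax.set_xlabel("candidate correction (ppm)")
    ax.set_ylabel("weighted composition residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
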