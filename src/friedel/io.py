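"""Readers and writers: reflection files (mmCIF-sf, TSV), substructure PDB,
phase tables, maps, truth records.

TSV dialect: '#' comment lines carry the cell, space group and label;
the data header is ``h k l f_plus sig_plus f_minus sig_minus free``.
Amplitudes are written to 6 decimal places and round-trip exactly at that
precision.  All writers emit a provenance/audit comment block (package
and format version; no timestamps, so outputs are byte-reproducible).
"""

from __future__ import annotations

import os

import numpy as np

from . import __version__ as _pkg_version
from .maps import MapGrid
from .reflections import PhaseDistribution, ReflectionSet
from .simulate import Site, Substructure, TruthRecord
from .symmetry import SpaceGroup, UnitCell

_TSV_COLUMNS = ["h", "k", "l", "f_plus", "sig_plus", "f_minus", "sig_minus", "free"]


def _provenance(kind: str) -> list[str]:
    return [
        f"# written by friedel {_pkg_version} ({kind})",
        "# format: 6-decimal amplitudes; '#' lines are comments",
    ]


# ----------------------------------------------------------------------
# reflections


def write_reflections(data, path, dialect: str = "tsv") -> None:
    """Write one ReflectionSet (or a list of them) to ``path``."""
    sets = data if isinstance(data, (list, tuple)) else [data]
    if dialect == "tsv":
        if len(sets) != 1:
            raise ValueError("the TSV dialect holds one wavelength set per file")
        _write_tsv(sets[0], path)
    elif dialect == "mmcif_sf":
        _write_mmcif(sets, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_reflections(path, dialect: str = "tsv") -> list[ReflectionSet]:
    """Read reflection set(s); mmCIF files may hold several wavelength
    blocks, each returned as its own ReflectionSet."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return [_read_tsv(path)]
    if dialect == "mmcif_sf":
        return _read_mmcif(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_tsv(data: ReflectionSet, path) -> None:
    c = data.cell
    lines = _provenance("reflections")
    lines.append(f"# cell: {c.a:.6f} {c.b:.6f} {c.c:.6f} {c.alpha:.6f} {c.beta:.6f} {c.gamma:.6f}")
    lines.append(f"# spacegroup: {data.sg.symbol}")
    lines.append(f"# label: {data.label}")
    lines.append("\t".join(_TSV_COLUMNS))
    for i in range(data.n):
        h, k, l = data.hkl[i]
        lines.append(
            f"{h}\t{k}\t{l}\t{data.f_plus[i]:.6f}\t{data.sig_plus[i]:.6f}\t"
            f"{data.f_minus[i]:.6f}\t{data.sig_minus[i]:.6f}\t{int(data.free[i])}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_tsv(path) -> ReflectionSet:
    cell = None
    sg = None
    label = "data"
    header = None
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("cell:"):
                    vals = [float(v) for v in body.split(":", 1)[1].split()]
                    cell = UnitCell(*vals)
                elif body.startswith("spacegroup:"):
                    sg = SpaceGroup(body.split(":", 1)[1].strip())
                elif body.startswith("label:"):
                    label = body.split(":", 1)[1].strip()
                continue
            if header is None:
                header = line.split()
                required = _TSV_COLUMNS[:-1]  # free optional
                missing = [c for c in required if c not in header]
                if missing:
                    raise ValueError(f"TSV missing required column(s): {', '.join(missing)}")
                continue
            rows.append(line.split())
    if cell is None or sg is None:
        raise ValueError("TSV lacks '# cell:' or '# spacegroup:' metadata")
    if header is None:
        raise ValueError("TSV has no header line")
    col = {name: header.index(name) for name in header}
    if not rows:
        z = np.zeros(0)
        return ReflectionSet(cell=cell, sg=sg, hkl=np.zeros((0, 3), dtype=int),
                             f_plus=z, sig_plus=z, f_minus=z, sig_minus=z, label=label)
    arr = np.array(rows, dtype=object)
    hkl = arr[:, [col["h"], col["k"], col["l"]]].astype(int)
    fp = arr[:, col["f_plus"]].astype(float)
    sp = arr[:, col["sig_plus"]].astype(float)
    fm = arr[:, col["f_minus"]].astype(float)
    sm = arr[:, col["sig_minus"]].astype(float)
    free = (
        arr[:, col["free"]].astype(int).astype(bool)
        if "free" in col
        else np.zeros(len(arr), dtype=bool)
    )
    return ReflectionSet(
        cell=cell, sg=sg, hkl=hkl, f_plus=fp, sig_plus=sp,
        f_minus=fm, sig_minus=sm, free=free, label=label,
    )


def _write_mmcif(sets, path) -> None:
    import gemmi.cif as cif

    doc = cif.Document()
    seen: set[str] = set()
    for j, data in enumerate(sets):
        name = f"refl_{data.label}"
        if name in seen:
            name = f"{name}_{j}"
        seen.add(name)
        block = doc.add_new_block(name)
        c = data.cell
        block.set_pair("_audit.creation_method", cif.quote(f"friedel {_pkg_version}"))
        for name, val in (
            ("_cell.length_a", c.a), ("_cell.length_b", c.b), ("_cell.length_c", c.c),
            ("_cell.angle_alpha", c.alpha), ("_cell.angle_beta", c.beta), ("_cell.angle_gamma", c.gamma),
        ):
            block.set_pair(name, f"{val:.6f}")
        block.set_pair("_symmetry.space_group_name_H-M", cif.quote(data.sg.symbol))
        loop = block.init_loop("_refln.", [
            "index_h", "index_k", "index_l",
            "pdbx_F_plus", "pdbx_F_plus_sigma",
            "pdbx_F_minus", "pdbx_F_minus_sigma",
            "status",
        ])
        for i in range(data.n):
            h, k, l = data.hkl[i]
            loop.add_row([
                str(h), str(k), str(l),
                f"{data.f_plus[i]:.6f}", f"{data.sig_plus[i]:.6f}",
                f"{data.f_minus[i]:.6f}", f"{data.sig_minus[i]:.6f}",
                "f" if data.free[i] else "o",
            ])
    doc.write_file(str(path))


def _read_mmcif(path) -> list[ReflectionSet]:
    import gemmi.cif as cif

    doc = cif.read(str(path))
    out = []
    for block in doc:
        a = block.find_pair("_cell.length_a")
        if a is None:
            continue
        cell = UnitCell(*[
            float(block.find_pair(f"_cell.{f}")[1])
            for f in ("length_a", "length_b", "length_c", "angle_alpha", "angle_beta", "angle_gamma")
        ])
        sg = SpaceGroup(cif.as_string(block.find_pair("_symmetry.space_group_name_H-M")[1]))
        cols = ["index_h", "index_k", "index_l", "pdbx_F_plus", "pdbx_F_plus_sigma",
                "pdbx_F_minus", "pdbx_F_minus_sigma"]
        table = block.find("_refln.", cols + ["status"])
        if not table:
            table = block.find("_refln.", cols)
            if not table:
                present = [c for c in cols if block.find_loop("_refln." + c)]
                missing = sorted(set(cols) - set(present))
                raise ValueError(f"mmCIF block missing _refln column(s): {', '.join(missing)}")
            has_status = False
        else:
            has_status = True
        rows = [[table[i][j] for j in range(len(cols) + int(has_status))] for i in range(len(table))]
        arr = np.array(rows, dtype=object)
        label = block.name.removeprefix("refl_")
        out.append(
            ReflectionSet(
                cell=cell, sg=sg,
                hkl=arr[:, 0:3].astype(int),
                f_plus=arr[:, 3].astype(float), sig_plus=arr[:, 4].astype(float),
                f_minus=arr[:, 5].astype(float), sig_minus=arr[:, 6].astype(float),
                free=(arr[:, 7] == "f") if has_status else None,
                label=label,
            )
        )
    if not out:
        raise ValueError("no reflection blocks found in mmCIF file")
    return out


# ----------------------------------------------------------------------
# substructures (minimal PDB)


def write_sites_pdb(sub: Substructure, cell: UnitCell, sg: SpaceGroup, path) -> None:
    M = cell.orthogonalization_matrix()
    lines = [
        f"REMARK   3 WRITTEN BY FRIEDEL {_pkg_version}",
        f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
        f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {sg.symbol:<11s}",
    ]
    for i, s in enumerate(sub.sites, start=1):
        xyz = M @ s.frac
        el = s.element.strip()[:2].rjust(2)
        lines.append(
            f"HETATM{i:5d} {el:>2s}   SUB A{i:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{s.occ:6.2f}{s.b:6.2f}"
            f"          {el:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sites_pdb(path, f_prime: float = 0.0, f_dprime: float = 0.0) -> tuple[Substructure, UnitCell, SpaceGroup]:
    cell = None
    sg = None
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                cell = UnitCell(
                    float(line[6:15]), float(line[15:24]), float(line[24:33]),
                    float(line[33:40]), float(line[40:47]), float(line[47:54]),
                )
                sg = SpaceGroup(line[55:66].strip())
            elif line.startswith(("HETATM", "ATOM")):
                if cell is None:
                    raise ValueError("PDB lacks CRYST1 before atom records")
                xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
                frac = np.linalg.solve(cell.orthogonalization_matrix(), xyz)
                frac = np.mod(frac, 1.0)
                element = line[76:78].strip() or line[12:14].strip()
                sites.append(
                    Site(element, *frac, occ=float(line[54:60]), b=float(line[60:66]),
                         f_prime=f_prime, f_dprime=f_dprime)
                )
    if cell is None or not sites:
        raise ValueError("no CRYST1/atom records found")
    return Substructure(sites), cell, sg


# ----------------------------------------------------------------------
# phases


def write_phases_tsv(phases: PhaseDistribution, path) -> None:
    lines = _provenance("phases")
    lines.append("h\tk\tl\tA\tB\tC\tD\tphi_best\tfom\tcentric")
    for i in range(phases.n):
        h, k, l = phases.hkl[i]
        A, B, C, D = phases.hl[i]
        lines.append(
            f"{h}\t{k}\t{l}\t{A:.6f}\t{B:.6f}\t{C:.6f}\t{D:.6f}\t"
            f"{phases.phi_best[i]:.6f}\t{phases.fom[i]:.6f}\t{int(phases.centric[i])}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_phases_tsv(path) -> PhaseDistribution:
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("h\t"):
                continue
            rows.append(line.split())
    arr = np.array(rows, dtype=float)
    return PhaseDistribution(
        arr[:, 0:3].astype(int), arr[:, 3:7], arr[:, 7], arr[:, 8], arr[:, 9].astype(bool)
    )


def write_phases_mmcif(phases: PhaseDistribution, data: ReflectionSet, path) -> None:
    import gemmi.cif as cif

    doc = cif.Document()
    block = doc.add_new_block("phases")
    block.set_pair("_audit.creation_method", cif.quote(f"friedel {_pkg_version}"))
    c = data.cell
    for name, val in (
        ("_cell.length_a", c.a), ("_cell.length_b", c.b), ("_cell.length_c", c.c),
        ("_cell.angle_alpha", c.alpha), ("_cell.angle_beta", c.beta), ("_cell.angle_gamma", c.gamma),
    ):
        block.set_pair(name, f"{val:.6f}")
    block.set_pair("_symmetry.space_group_name_H-M", cif.quote(data.sg.symbol))
    loop = block.init_loop("_refln.", [
        "index_h", "index_k", "index_l",
        "pdbx_HL_A_iso", "pdbx_HL_B_iso", "pdbx_HL_C_iso", "pdbx_HL_D_iso",
        "phase_meas", "fom",
    ])
    for i in range(phases.n):
        h, k, l = phases.hkl[i]
        A, B, C, D = phases.hl[i]
        loop.add_row([
            str(h), str(k), str(l),
            f"{A:.6f}", f"{B:.6f}", f"{C:.6f}", f"{D:.6f}",
            f"{phases.phi_best[i]:.6f}", f"{phases.fom[i]:.6f}",
        ])
    doc.write_file(str(path))


# ----------------------------------------------------------------------
# misc tables / maps


def write_fa_tsv(fa, path) -> None:
    lines = _provenance("fa_estimate")
    lines.append(f"# method: {fa.method}")
    lines.append("h\tk\tl\tfa\tsig_fa\te_norm\tuse")
    for i in range(fa.n):
        h, k, l = fa.hkl[i]
        lines.append(
            f"{h}\t{k}\t{l}\t{fa.fa[i]:.6f}\t{fa.sig_fa[i]:.6f}\t{fa.e_norm[i]:.6f}\t{int(fa.use[i])}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_signal_table(table, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance("signal_by_shell")) + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_trial_log(trials, path) -> None:
    lines = _provenance("search_trials")
    lines.append("trial\tseed\tscore\tn_sites")
    for t in trials:
        lines.append(f"{t.trial_id}\t{t.seed}\t{t.score:.6f}\t{t.sites.n_sites}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_map_ccp4(grid: MapGrid, path) -> None:
    """CCP4/MRC map via gemmi (binary; runtime output only)."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(
        grid.cell.a, grid.cell.b, grid.cell.c,
        grid.cell.alpha, grid.cell.beta, grid.cell.gamma,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_truth_tsv(truth: TruthRecord, path) -> None:
    """Ground-truth companion table (first channel)."""
    label = next(iter(truth.f_plus_true))
    lines = _provenance("truth_record")
    lines.append(f"# channel: {label}")
    lines.append("h\tk\tl\tphi_p\tf_plus_true\tf_minus_true\tf_h_amp\tcentric")
    fh_amp = np.abs(truth.f_h_plus[label])
    for i in range(len(truth.hkl)):
        h, k, l = truth.hkl[i]
        lines.append(
            f"{h}\t{k}\t{l}\t{truth.phi_p[i]:.6f}\t{truth.f_plus_true[label][i]:.6f}\t"
            f"{truth.f_minus_true[label][i]:.6f}\t{fh_amp[i]:.6f}\t{int(truth.centric[i])}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
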