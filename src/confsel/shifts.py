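"""Chemical-shift based secondary-structure analysis and CSP mapping.

Covers secondary shifts against random-coil references, windowed secondary
structure propensity (SSP) scores, chemical shift index (CSI) consensus,
helix populations from 3J(HN-HA) couplings, NOE intensity-ratio
classification and weighted-average chemical shift perturbations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShiftRecord",
    "ShiftTable",
    "RandomCoilTable",
    "SSPProfile",
    "JCoupling",
    "CSPRecord",
    "load_random_coil_table",
    "load_random_coil_j",
    "secondary_shifts",
    "ssp",
    "csi",
    "helix_population_from_J",
    "karplus_3J",
    "noe_ratio_classify",
    "csp",
    "read_shift_tsv",
    "write_shift_tsv",
    "read_nmrstar_shifts",
]

SHIFT_WINDOWS = {
    "HN": (5.0, 12.0),
    "N": (100.0, 140.0),
    "HA": (2.5, 6.5),
    "CA": (40.0, 75.0),
    "CB": (10.0, 80.0),
    "CO": (165.0, 185.0),
}

AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()
AA1TO3 = dict(zip("ARNDCQEGHILKMFPSTWYV", AA3))
AA3TO1 = {v: k for k, v in AA1TO3.items()}


@dataclass(frozen=True)
class ShiftRecord:
    residue_number: int
    residue_name: str
    atom: str
    shift: float

    def __post_init__(self) -> None:
        lo, hi = SHIFT_WINDOWS.get(self.atom, (-1e9, 1e9))
        if not (lo <= self.shift <= hi):
            raise ValueError(
                f"{self.atom} shift {self.shift} ppm outside plausible window [{lo}, {hi}] "
                f"(residue {self.residue_number})"
            )


class ShiftTable:
    """Per-residue, per-atom chemical shifts for one molecular state."""

    def __init__(self, records: Iterable[ShiftRecord], state: str = "") -> None:
        self.records = list(records)
        self.state = state
        keys = [(r.residue_number, r.atom) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue, atom) shift entries")
        self._by_key = {(r.residue_number, r.atom): r for r in self.records}
        self._restype = {r.residue_number: r.residue_name for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def residues(self) -> list[int]:
        return sorted(self._restype)

    def residue_name(self, residue: int) -> str:
        return self._restype[residue]

    def get(self, residue: int, atom: str) -> float | None:
        rec = self._by_key.get((residue, atom))
        return rec.shift if rec else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "residue_number": r.residue_number,
                    "residue_name": r.residue_name,
                    "atom": r.atom,
                    "shift_ppm": r.shift,
                }
                for r in self.records
            ]
        )


class RandomCoilTable:
    """Random-coil shifts plus full-helix/full-strand secondary-shift values.

    Indexed by (3-letter residue type, atom). Secondary-shift values are
    signed: e.g. CA helix positive, HA helix negative.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"residue_name", "atom", "rc_ppm", "helix_full_ppm", "strand_full_ppm"}
        if not required.issubset(frame.columns):
            raise ValueError(f"random-coil table missing columns {required - set(frame.columns)}")
        self._frame = frame
        self._rc = {(r.residue_name, r.atom): r.rc_ppm for r in frame.itertuples()}
        self._helix = {(r.residue_name, r.atom): r.helix_full_ppm for r in frame.itertuples()}
        self._strand = {(r.residue_name, r.atom): r.strand_full_ppm for r in frame.itertuples()}
        for res in AA3:
            for atom in ("CA", "HA"):
                if (res, atom) not in self._rc:
                    raise ValueError(f"random-coil table incomplete: missing {res}/{atom}")
            if res != "GLY" and (res, "CB") not in self._rc:
                raise ValueError(f"random-coil table incomplete: missing {res}/CB")

    def rc(self, residue_name: str, atom: str) -> float | None:
        return self._rc.get((residue_name, atom))

    def helix_full(self, residue_name: str, atom: str) -> float | None:
        return self._helix.get((residue_name, atom))

    def strand_full(self, residue_name: str, atom: str) -> float | None:
        return self._strand.get((residue_name, atom))


def load_random_coil_table() -> RandomCoilTable:
    """Load the packaged random-coil reference table."""
    with resources.files("confsel.data").joinpath("random_coil.tsv").open() as fh:
        return RandomCoilTable(pd.read_csv(fh, sep="\t"))


def load_random_coil_j() -> dict[str, float]:
    """Per-residue-type random-coil 3J(HN-HA) reference values in Hz."""
    with resources.files("confsel.data").joinpath("random_coil_j.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df.residue_name, df.j_coil_hz))


# ---------------------------------------------------------------------------
# Secondary shifts and SSP
# ---------------------------------------------------------------------------

SSP_ATOMS_DEFAULT = ("CA", "CB")


def secondary_shifts(obs: ShiftTable, rc: RandomCoilTable, atoms: Sequence[str] = ("CA", "CB", "HA")) -> pd.DataFrame:
    """Observed minus random-coil shifts per residue for the requested atoms.

    Residues missing either the observed or the reference value get NaN and
    are listed in the ``skipped`` attribute of the returned frame.
    """
    rows = []
    skipped: list[tuple[int, str]] = []
    for res in obs.residues:
        rt = obs.residue_name(res)
        if rt not in AA3:
            raise ValueError(f"unknown residue type {rt!r} at residue {res}")
        row: dict = {"residue_number": res, "residue_name": rt}
        for atom in atoms:
            o = obs.get(res, atom)
            r = rc.rc(rt, atom)
            if o is None or r is None:
                row[f"dd_{atom}"] = np.nan
                skipped.append((res, atom))
            else:
                row[f"dd_{atom}"] = o - r
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


@dataclass
class SSPProfile:
    """Windowed secondary-structure propensity scores (+helix / -strand)."""

    scores: pd.Series  # index: residue_number
    window: int
    atoms: tuple[str, ...]
    overshoot_flags: list[int]

    def region_mean(self, start: int, end: int) -> float:
        sel = self.scores.loc[[r for r in self.scores.index if start <= r <= end]]
        return float(sel.mean())


def ssp(
    obs: ShiftTable,
    rc: RandomCoilTable,
    window: int = 5,
    atoms: Sequence[str] = SSP_ATOMS_DEFAULT,
) -> SSPProfile:
    """Secondary structure propensity score per residue.

    For each residue a window of neighbors is pooled; each atom's secondary
    shift is oriented along its helix direction and the pooled sum is
    normalized by the corresponding fully-formed secondary-shift magnitudes
    (helix magnitudes if the pooled shift points helixward, strand magnitudes
    otherwise). A fully formed helix scores +1, a fully formed strand -1.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    sec = secondary_shifts(obs, rc, atoms=atoms)
    residues = sec["residue_number"].tolist()
    usable = sec[[f"dd_{a}" for a in atoms]].notna().any(axis=1).sum()
    if usable < window:
        raise ValueError(f"not enough usable shifts ({usable}) for window {window}")
    sec = sec.set_index("residue_number")
    half = window // 2
    scores: dict[int, float] = {}
    overshoot: list[int] = []
    for i, res in enumerate(residues):
        lo, hi = max(0, i - half), min(len(residues), i + half + 1)
        num = 0.0
        den_h = 0.0
        den_s = 0.0
        for j in range(lo, hi):
            rj = residues[j]
            rt = sec.at[rj, "residue_name"]
            for atom in atoms:
                dd = sec.at[rj, f"dd_{atom}"]
                h = rc.helix_full(rt, atom)
                s = rc.strand_full(rt, atom)
                if dd is None or h is None or s is None or not np.isfinite(dd):
                    continue
                sign = math.copysign(1.0, h)
                num += dd * sign
                den_h += abs(h)
                den_s += abs(s)
        if den_h == 0:
            scores[res] = np.nan
            continue
        score = num / den_h if num >= 0 else num / den_s
        if abs(score) > 1.1:
            overshoot.append(res)
        scores[res] = score
    series = pd.Series(scores).sort_index()
    if overshoot:
        warnings.warn(f"SSP scores outside [-1.1, 1.1] at residues {overshoot}", UserWarning, stacklevel=2)
    return SSPProfile(scores=series, window=window, atoms=tuple(atoms), overshoot_flags=overshoot)


# ---------------------------------------------------------------------------
# CSI
# ---------------------------------------------------------------------------

CSI_THRESHOLDS = {"CA": 0.7, "HA": 0.1}
# +1 = helix-indicating, -1 = strand-indicating (HA sign convention is
# inverted relative to CA: helix shifts HA upfield).
_CSI_HELIX_SIGN = {"CA": +1.0, "HA": -1.0}


def csi(obs: ShiftTable, rc: RandomCoilTable) -> pd.DataFrame:
    """Chemical shift index per residue plus a consensus structure string.

    Per-atom index is +1 (helix-like), -1 (strand-like) or 0 from thresholded
    secondary shifts (CA: +/-0.7 ppm, HA: +/-0.1 ppm). Consensus: residues in
    a run of >= 4 consecutive helix-indicating combined indices are "H", runs
    of >= 3 strand-indicating are "E", otherwise "C". The result frame carries
    the consensus string in ``attrs["consensus"]``.
    """
    sec = secondary_shifts(obs, rc, atoms=("CA", "HA"))
    rows = []
    for _, r in sec.iterrows():
        idx: dict = {"residue_number": int(r.residue_number), "residue_name": r.residue_name}
        combined = 0
        for atom, thr in CSI_THRESHOLDS.items():
            dd = r[f"dd_{atom}"]
            if not np.isfinite(dd) or abs(dd) < thr:
                idx[f"csi_{atom}"] = 0
            else:
                idx[f"csi_{atom}"] = int(_CSI_HELIX_SIGN[atom] * math.copysign(1, dd))
            combined += idx[f"csi_{atom}"]
        idx["csi"] = int(np.sign(combined))
        rows.append(idx)
    out = pd.DataFrame(rows)
    c = out["csi"].tolist()
    consensus = ["C"] * len(c)
    i = 0
    while i < len(c):
        if c[i] != 0:
            j = i
            while j < len(c) and c[j] == c[i]:
                j += 1
            run = j - i
            if c[i] > 0 and run >= 4:
                consensus[i:j] = ["H"] * run
            elif c[i] < 0 and run >= 3:
                consensus[i:j] = ["E"] * run
            i = j
        else:
            i += 1
    out["consensus"] = consensus
    out.attrs["consensus"] = "".join(consensus)
    return out


# ---------------------------------------------------------------------------
# J couplings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JCoupling:
    residue_number: int
    value: float
    error: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 12.0):
            raise ValueError(f"3J value {self.value} Hz outside [0, 12]")


J_HELIX_DEFAULT = 4.0
KARPLUS_DEFAULT = (6.51, -1.76, 1.60)  # A, B, C in Hz


def karplus_3J(phi_deg: float, params: tuple[float, float, float] = KARPLUS_DEFAULT) -> float:
    """3J(HN-HA) from the backbone phi dihedral: A cos^2(phi-60) + B cos(phi-60) + C."""
    a, b, c = params
    x = math.cos(math.radians(phi_deg - 60.0))
    return a * x * x + b * x + c


def helix_population_from_J(
    couplings: Sequence[JCoupling],
    restypes: dict[int, str],
    j_helix: float = J_HELIX_DEFAULT,
    j_coil: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Two-state helix population per residue: p = (Jcoil - Jobs)/(Jcoil - Jhelix).

    Values are clipped to [0, 1]; clipped residues are flagged in the
    ``clipped`` column.
    """
    if j_coil is None:
        j_coil = load_random_coil_j()
    rows = []
    for jc in couplings:
        rt = restypes[jc.residue_number]
        jc_coil = j_coil[rt] if isinstance(j_coil, dict) else float(j_coil)
        if jc_coil == j_helix:
            raise ValueError("j_coil equals j_helix; population undefined")
        p = (jc_coil - jc.value) / (jc_coil - j_helix)
        clipped = p < 0 or p > 1
        rows.append(
            {
                "residue_number": jc.residue_number,
                "j_obs_hz": jc.value,
                "j_coil_hz": jc_coil,
                "population": float(np.clip(p, 0.0, 1.0)),
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NOE intensity ratios
# ---------------------------------------------------------------------------

NOE_REF = {"helix": 0.25, "coil": 1.4, "strand": 55.0}


def noe_ratio_classify(ratios: dict[int, float]) -> pd.DataFrame:
    """Classify sequential-NOE intensity ratios by nearest reference in log space.

    The reference aH-HN(i,i+1)/HN-HN(i,i+1) ratios are 0.25 (helix), 1.4
    (random coil) and 55 (strand); the helix fraction is a log-linear
    interpolation between the helix and coil references, clipped to [0, 1].
    """
    rows = []
    log_refs = {k: math.log(v) for k, v in NOE_REF.items()}
    lh, lc = log_refs["helix"], log_refs["coil"]
    for res, ratio in sorted(ratios.items()):
        if ratio <= 0:
            raise ValueError(f"nonpositive NOE intensity ratio at residue {res}")
        lr = math.log(ratio)
        cls = min(log_refs, key=lambda k: abs(lr - log_refs[k]))
        frac = float(np.clip((lc - lr) / (lc - lh), 0.0, 1.0))
        rows.append({"residue_number": res, "ratio": ratio, "class": cls, "helix_fraction": frac})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CSPRecord:
    residue_number: int
    delta_HN: float
    delta_N: float
    delta_obs: float
    intensity_ratio: float | None = None


N_SCALE = 25.0  # nitrogen shift variance scale in the weighted average


def csp(
    free: ShiftTable,
    bound: ShiftTable,
    intensity_ratios: dict[int, float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Weighted-average amide chemical shift perturbation per residue.

    delta_obs = sqrt[(ddHN^2 + ddN^2/25)/2] from the HN and N shift changes
    between the two states. Returns the per-residue table and the mean
    delta_obs over the residues observed in both states. Residues present in
    only one table are excluded and listed in ``attrs["excluded"]``.
    """
    rows = []
    excluded: list[int] = []
    for res in sorted(set(free.residues) | set(bound.residues)):
        f_hn, f_n = free.get(res, "HN"), free.get(res, "N")
        b_hn, b_n = bound.get(res, "HN"), bound.get(res, "N")
        if None in (f_hn, f_n, b_hn, b_n):
            excluded.append(res)
            continue
        d_hn = abs(b_hn - f_hn)
        d_n = abs(b_n - f_n)
        d_obs = math.sqrt((d_hn**2 + d_n**2 / N_SCALE) / 2.0)
        rows.append(
            {
                "residue_number": res,
                "delta_HN": d_hn,
                "delta_N": d_n,
                "delta_obs": d_obs,
                "intensity_ratio": (intensity_ratios or {}).get(res, np.nan),
            }
        )
    if not rows:
        raise ValueError("no residues shared between the two shift tables")
    table = pd.DataFrame(rows)
    table.attrs["excluded"] = excluded
    return table, float(table["delta_obs"].mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_shift_tsv(path, state: str = "") -> ShiftTable:
    df = pd.read_csv(path, sep="\t")
    return ShiftTable(
        [
            ShiftRecord(int(r.residue_number), str(r.residue_name), str(r.atom), float(r.shift_ppm))
            for r in df.itertuples()
        ],
        state=state,
    )


def write_shift_tsv(table: ShiftTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


_STAR_ATOM_MAP = {"H": "HN", "HN": "HN", "N": "N", "HA": "HA", "CA": "CA", "CB": "CB", "C": "CO"}


def read_nmrstar_shifts(path, entity_id: int | None = None) -> ShiftTable:
    """Minimal NMR-STAR v3 reader for assigned chemical-shift loops.

    Parses ``_Atom_chem_shift`` loops from BMRB entry files; only backbone
    atoms used by this package (HN, N, HA, CA, CB, CO) are retained.
    """
    with open(path) as fh:
        text = fh.read()
    records: list[ShiftRecord] = []
    seen: set[tuple[int, str]] = set()
    lines = iter(text.splitlines())
    for line in lines:
        if line.strip() != "loop_":
            continue
        tags: list[str] = []
        for line in lines:
            t = line.strip()
            if t.startswith("_"):
                tags.append(t.split(".")[-1] if "." in t else t.lstrip("_"))
            else:
                break
        if "Atom_chem_shift" not in text or "Val" not in tags or "Atom_ID" not in tags:
            continue
        needed = {"Seq_ID", "Comp_ID", "Atom_ID", "Val"}
        if not needed.issubset(tags):
            continue
        idx = {k: tags.index(k) for k in tags}
        rows = [line] if line.strip() and not line.strip().startswith(("stop_", "#")) else []
        for line in lines:
            t = line.strip()
            if t.startswith("stop_") or not t:
                break
            rows.append(line)
        for row in rows:
            fields = row.split()
            if len(fields) < len(tags):
                continue
            if entity_id is not None and "Entity_ID" in idx:
                try:
                    if int(fields[idx["Entity_ID"]]) != entity_id:
                        continue
                except ValueError:
                    continue
            atom = _STAR_ATOM_MAP.get(fields[idx["Atom_ID"]])
            if atom is None:
                continue
            try:
                res = int(fields[idx["Seq_ID"]])
                val = float(fields[idx["Val"]])
            except ValueError:
                continue
            if (res, atom) in seen:
                continue
            seen.add((res, atom))
            records.append(ShiftRecord(res, fields[idx["Comp_ID"]], atom, val))
    if not records:
        raise ValueError(f"no assigned chemical shifts found in {path}")
    return ShiftTable(records, state=f"nmrstar:{path}")
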