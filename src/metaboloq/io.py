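"""File formats: network configs, trajectory CSVs, traces, FASTA, TSV tables.

All CSV/TSV output is comma/tab separated, ``.`` decimal, UTF-8, LF —
fixed, never locale-dependent.  Floats are written with ``repr`` so that a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .fitting import ObservedTrace
from .network import (
    GeneralizedReaction,
    ParameterDef,
    ReactionNetwork,
    SpeciesDef,
    make_network,
)
from .simulate import Trajectory
from .stoich import PSMTable, ProteinEntry

__all__ = [
    "read_network_config",
    "write_network_config",
    "write_trajectory",
    "read_trajectory",
    "write_trace_csv",
    "read_trace_csv",
    "write_fasta",
    "read_proteins",
    "write_complex_map",
    "write_psm_table",
    "read_psm_table",
    "write_manifest",
]


class ParseError(ValueError):
    """A file does not conform to its schema."""


# ---------------------------------------------------------------------------
# network configuration
# ---------------------------------------------------------------------------

_NETWORK_KEYS = {"species", "parameters", "reactions"}


def _network_from_dict(doc: dict) -> ReactionNetwork:
    if not isinstance(doc, dict):
        raise ParseError("network config must be a mapping")
    unknown = set(doc) - _NETWORK_KEYS
    if unknown:
        raise ParseError(f"unknown network config keys: {sorted(unknown)}")
    missing = _NETWORK_KEYS - set(doc)
    if missing:
        raise ParseError(f"network config missing keys: {sorted(missing)}")
    try:
        species = [
            SpeciesDef(str(s["id"]), str(s.get("name", s["id"])), float(s["initial"]))
            for s in doc["species"]
        ]
        params = [ParameterDef(str(p["id"]), float(p["value"])) for p in doc["parameters"]]
        reactions = [
            GeneralizedReaction(
                str(r["id"]),
                str(r["k"]),
                tuple((str(sp), int(e)) for sp, e in r["rate_factors"]),
                {str(sp): int(v) for sp, v in r["stoich"].items()},
            )
            for r in doc["reactions"]
        ]
    except KeyError as err:
        raise ParseError(f"network config entry missing key {err}") from None
    return make_network(species, params, reactions)


def read_network_config(path: str | Path) -> ReactionNetwork:
    """Load a network from a YAML/JSON config; ``"canonical"`` loads the packaged file."""
    if str(path) == "canonical":
        ref = importlib.resources.files("metaboloq.data") / "canonical_qcycle.yaml"
        doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return _network_from_dict(doc)
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)  # YAML is a JSON superset
    return _network_from_dict(doc)


def write_network_config(network: ReactionNetwork, path: str | Path) -> None:
    doc = {
        "species": [
            {"id": s.id, "name": s.name, "initial": float(s.initial)}
            for s in network.species
        ],
        "parameters": [
            {"id": p.id, "value": float(p.value)} for p in network.parameters
        ],
        "reactions": [
            {
                "id": r.id,
                "k": r.rate_constant,
                "rate_factors": [[sp, int(e)] for sp, e in r.rate_factors],
                "stoich": {sp: int(v) for sp, v in r.stoichiometry.items()},
            }
            for r in network.reactions
        ],
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=None),
        encoding="utf-8", newline="\n",
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(trajectory: Trajectory, path: str | Path,
                     species_names: dict[str, str] | None = None) -> None:
    """CSV with a scenario comment line, ``t,x1:NAME,...`` header, repr-exact floats."""
    names = species_names or {}
    header = ["t"] + [
        f"{sid}:{names.get(sid, sid)}" for sid in trajectory.species_ids
    ]
    lines = [f"# scenario={trajectory.scenario}", ",".join(header)]
    for t, row in zip(trajectory.times, trajectory.states):
        lines.append(",".join([repr(float(t))] + [repr(float(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory`; lossless for repr-exact floats."""
    raw = Path(path).read_text(encoding="utf-8").splitlines()
    if not raw:
        raise ParseError(f"{path}: empty trajectory file")
    scenario = "custom"
    i = 0
    if raw[0].startswith("#"):
        if "scenario=" in raw[0]:
            scenario = raw[0].split("scenario=", 1)[1].strip()
        i = 1
    if i >= len(raw):
        raise ParseError(f"{path}: missing header line")
    header = raw[i].split(",")
    if header[0] != "t" or len(header) < 2:
        raise ParseError(f"{path}: line {i + 1}: header must start with 't'")
    species_ids = [h.split(":", 1)[0] for h in header[1:]]
    times, states = [], []
    for ln, line in enumerate(raw[i + 1:], start=i + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise ParseError(
                f"{path}: line {ln}: expected {len(header)} fields, got {len(parts)}"
            )
        try:
            vals = [float(p) for p in parts]
        except ValueError as err:
            raise ParseError(f"{path}: line {ln}: {err}") from None
        times.append(vals[0])
        states.append(vals[1:])
    if not times:
        raise ParseError(f"{path}: no data rows")
    times_a = np.array(times)
    if np.any(np.diff(times_a) <= 0):
        raise ParseError(f"{path}: times are not strictly increasing")
    return Trajectory(
        times=times_a,
        states=np.array(states),
        species_ids=species_ids,
        scenario=scenario,
        settings=None,
        diagnostics={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# traces (2-column CSV)
# ---------------------------------------------------------------------------

def write_trace_csv(trace: ObservedTrace, path: str | Path) -> None:
    lines = ["t,signal"] + [
        f"{repr(float(t))},{repr(float(s))}"
        for t, s in zip(trace.times, trace.signal)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_trace_csv(path: str | Path) -> ObservedTrace:
    """2-column ``t,signal`` CSV, optional header row."""
    raw = [l for l in Path(path).read_text(encoding="utf-8").splitlines() if l.strip()]
    if not raw:
        raise ParseError(f"{path}: empty trace file")
    start = 0
    try:
        float(raw[0].split(",")[0])
    except ValueError:
        start = 1
    times, signal = [], []
    for ln, line in enumerate(raw[start:], start=start + 1):
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {ln}: expected 2 fields, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            signal.append(float(parts[1]))
        except ValueError as err:
            raise ParseError(f"{path}: line {ln}: {err}") from None
    if not times:
        raise ParseError(f"{path}: no data rows")
    return ObservedTrace(times=np.array(times), signal=np.array(signal))


# ---------------------------------------------------------------------------
# proteomics fixtures
# ---------------------------------------------------------------------------

def write_fasta(proteins: list[ProteinEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=f"complex={p.complex_label}")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def write_complex_map(proteins: list[ProteinEntry], path: str | Path) -> None:
    lines = ["protein_id\tcomplex"] + [
        f"{p.id}\t{p.complex_label}" for p in proteins
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_proteins(fasta_path: str | Path, complex_map_path: str | Path,
                  response_factors: dict[str, float] | None = None) -> list[ProteinEntry]:
    """Assemble :class:`ProteinEntry` list from a FASTA file and a TSV complex map."""
    cmap = pd.read_csv(complex_map_path, sep="\t", dtype=str)
    if not {"protein_id", "complex"} <= set(cmap.columns):
        raise ParseError(
            f"{complex_map_path}: need columns 'protein_id' and 'complex'"
        )
    labels = dict(zip(cmap["protein_id"], cmap["complex"]))
    rf = response_factors or {}
    proteins = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in labels:
            raise ParseError(f"{fasta_path}: {rec.id!r} missing from complex map")
        proteins.append(
            ProteinEntry(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                complex_label=labels[rec.id],
                response_factor=float(rf.get(rec.id, 1.0)),
            )
        )
    return proteins


def write_psm_table(table: PSMTable, path: str | Path) -> None:
    lines = ["protein_id\tpsm_count"] + [
        f"{pid}\t{c}" for pid, c in table.counts.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_psm_table(path: str | Path) -> PSMTable:
    df = pd.read_csv(path, sep="\t")
    if not {"protein_id", "psm_count"} <= set(df.columns):
        raise ParseError(f"{path}: need columns 'protein_id' and 'psm_count'")
    return PSMTable.from_rows(
        (str(r.protein_id), int(r.psm_count)) for r in df.itertuples()
    )


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def write_manifest(out_dir: str | Path, command: str, params: dict,
                   seed: int | None = None) -> Path:
    """Machine-readable record sufficient to re-run a pipeline command."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "metaboloq",
        "version": __version__,
        "command": command,
        "parameters": params,
        "seed": seed,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8", newline="\n")
    return path
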