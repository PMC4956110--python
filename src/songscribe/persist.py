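"""Persistence: HDF5 for spectrograms, scores and network parameters;
plain-text tables for syntax models."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .architecture import ArchitectureSpec, build_architecture
from .classifier import ClassifierEnsemble, ScoreMatrix
from .nnet import Network
from .signal_features import NormalizationStats, Spectrogram, SpectrogramParams
from .syntax import SyntaxModel

__all__ = [
    "save_spectrogram", "load_spectrogram",
    "save_scores", "load_scores",
    "save_ensemble", "load_ensemble",
    "save_syntax_model", "load_syntax_model",
]

_PARAM_FIELDS = ("sample_rate", "fft_size", "hop", "taper_half_bandwidth",
                 "band_low", "band_high", "log_floor")


def _write_params(group, params: SpectrogramParams) -> None:
    for f in _PARAM_FIELDS:
        group.attrs[f] = getattr(params, f)


def _read_params(group) -> SpectrogramParams:
    return SpectrogramParams(**{f: group.attrs[f] for f in _PARAM_FIELDS})


def save_spectrogram(path, spec: Spectrogram) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=spec.values)
        _write_params(d, spec.params)
        d.attrs["normalized"] = spec.normalized


def load_spectrogram(path) -> Spectrogram:
    with h5py.File(path, "r") as f:
        d = f["values"]
        return Spectrogram(values=d[...], params=_read_params(d),
                           normalized=bool(d.attrs["normalized"]))


def save_scores(path, sm: ScoreMatrix) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("scores", data=sm.scores)
        d.attrs["frame_ms"] = sm.frame_ms


def load_scores(path) -> ScoreMatrix:
    with h5py.File(path, "r") as f:
        d = f["scores"]
        return ScoreMatrix(scores=d[...], frame_ms=float(d.attrs["frame_ms"]))


def save_ensemble(path, ens: ClassifierEnsemble) -> None:
    arch = ens.architecture
    with h5py.File(path, "w") as f:
        f.attrs["arrangement"] = arch.arrangement
        f.attrs["n_note_classes"] = arch.n_note_classes
        f.attrs["input_height"] = arch.input_height
        f.attrs["classes"] = np.array(ens.classes, dtype=h5py.string_dtype())
        f.attrs["norm_per_row"] = ens.normalization.per_row
        f.create_dataset("norm_mean", data=np.asarray(ens.normalization.mean))
        f.create_dataset("norm_std", data=np.asarray(ens.normalization.std))
        for i, net in enumerate(ens.members):
            g = f.create_group(f"member_{i}")
            g.attrs["seed"] = net.seed
            for j, p in enumerate(net.parameters()):
                g.create_dataset(f"p{j}", data=p)


def load_ensemble(path) -> ClassifierEnsemble:
    with h5py.File(path, "r") as f:
        arch = build_architecture(str(f.attrs["arrangement"]),
                                  int(f.attrs["n_note_classes"]),
                                  int(f.attrs["input_height"]))
        stats = NormalizationStats(mean=f["norm_mean"][...], std=f["norm_std"][...],
                                   per_row=bool(f.attrs["norm_per_row"]))
        members = []
        i = 0
        while f"member_{i}" in f:
            g = f[f"member_{i}"]
            net = Network(arch, int(g.attrs["seed"]))
            state = [g[f"p{j}"][...] for j in range(len(net.parameters()))]
            net.set_state(state)
            members.append(net)
            i += 1
        classes = [c.decode() if isinstance(c, bytes) else str(c)
                   for c in f.attrs["classes"]]
    return ClassifierEnsemble(members=members, architecture=arch,
                              normalization=stats, classes=classes)


def save_syntax_model(path, model: SyntaxModel) -> None:
    """Plain-text table: context X Y, class Z, probability."""
    lines = [f"# alpha\t{model.alpha}", "# classes\t" + "\t".join(model.classes)]
    for x, cx in enumerate(model.classes):
        for y, cy in enumerate(model.classes):
            for z, cz in enumerate(model.classes):
                lines.append(f"{cx}\t{cy}\t{cz}\t{model.trans[x, y, z]:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_syntax_model(path) -> SyntaxModel:
    lines = Path(path).read_text().splitlines()
    alpha = float(lines[0].split("\t")[1])
    classes = lines[1].split("\t")[1:]
    n = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    trans = np.zeros((n, n, n))
    for line in lines[2:]:
        if not line.strip():
            continue
        x, y, z, p = line.split("\t")
        trans[idx[x], idx[y], idx[z]] = float(p)
    return SyntaxModel(classes=classes, alpha=alpha, trans=trans)
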