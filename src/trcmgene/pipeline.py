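"""End-to-end compression pipeline: digitize -> cluster -> partition ->
reference selection -> diff encoding -> container assembly, and the inverse.

This is the library surface the command-line interface wraps; everything
here works on paths or in-memory objects and is deterministic given the
configured seed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CorruptionError, ParameterError
from .clustering import kmeans_cluster
from .container import (
    compression_factor,
    read_container,
    write_container,
)
from .genotype_io import (
    GenotypeMatrix,
    digitize,
    infer_marker_info,
    read_ped,
    undigitize,
    write_ped,
)
from .refsel import KIND_PEER, ZONE_AI, ZONE_AII, ZONE_B, assign_references

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one compression run; echoed into the container header."""

    mode: str = "trcm"            # "trcm" or "orcm"
    k: int = 5                    # number of clusters / core sequences
    q1: float = 0.8               # quantile for T1 (unless t1 explicit)
    q2: float = 0.5               # quantile for T2 (unless t2 explicit)
    t1: float | None = None       # explicit thresholds applied to all clusters
    t2: float | None = None
    delta_d: float | None = None  # block radius increment (default ring/4)
    knn_k: int = 1
    block_size: int = 64
    deflate: bool = True
    seed: int = 0
    dialect: str = "ped"
    name: str = ""
    description: str = ""

    def as_params(self) -> dict:
        return {
            "mode": self.mode, "k": self.k, "q1": self.q1, "q2": self.q2,
            "t1": self.t1, "t2": self.t2, "delta_d": self.delta_d,
            "knn_k": self.knn_k, "block_size": self.block_size,
            "seed": self.seed,
        }


@dataclass
class CompressionReport:
    """Summary of one compression run."""

    n_individuals: int
    n_markers: int
    k: int
    mode: str
    zone_counts: dict = field(default_factory=dict)
    peer_fraction: float = 0.0
    container_bytes: int = 0
    factor: float | None = None
    cluster_params: list = field(default_factory=list)


def compress_matrix(matrix: GenotypeMatrix, out_path,
                    config: RunConfig | None = None) -> CompressionReport:
    """Compress an in-memory digitized panel to a container file/stream."""
    config = config or RunConfig()
    if config.mode not in ("trcm", "orcm"):
        raise ParameterError(f"mode must be 'trcm' or 'orcm', got {config.mode!r}")
    n = matrix.n_individuals
    report = CompressionReport(n_individuals=n, n_markers=matrix.n_markers,
                               k=0, mode=config.mode)
    if n == 0:
        report.container_bytes = write_container(
            matrix, None, None, out_path, block_size=config.block_size,
            deflate=config.deflate, name=config.name,
            description=config.description, mode=config.mode,
            params=config.as_params())
        return report

    k = min(config.k, n)
    if k < config.k:
        logger.info("k reduced from %d to %d (panel has %d sequences)",
                    config.k, k, n)
    model = kmeans_cluster(matrix, k, seed=config.seed)
    thresholds = None
    if config.t1 is not None and config.t2 is not None:
        thresholds = [(config.t1, config.t2)] * k
    assignment = assign_references(
        matrix, model, mode=config.mode, thresholds=thresholds,
        q1=config.q1, q2=config.q2, delta_d=config.delta_d,
        knn_k=config.knn_k)
    report.k = k
    report.zone_counts = {
        "A_I": int((assignment.zone == ZONE_AI).sum()),
        "A_II": int((assignment.zone == ZONE_AII).sum()),
        "B": int((assignment.zone == ZONE_B).sum()),
    }
    report.peer_fraction = assignment.peer_fraction
    report.cluster_params = assignment.cluster_params
    report.container_bytes = write_container(
        matrix, model, assignment, out_path, block_size=config.block_size,
        deflate=config.deflate, name=config.name,
        description=config.description, mode=config.mode,
        params=config.as_params())
    logger.info("compressed %d x %d panel: %d bytes, peer fraction %.3f",
                n, matrix.n_markers, report.container_bytes,
                report.peer_fraction)
    return report


def compress_files(ped_path, out_path, map_path=None,
                   config: RunConfig | None = None) -> CompressionReport:
    """Compress PED/MAP (or TSV) files; reports the compression factor."""
    config = config or RunConfig()
    raw = read_ped(ped_path, map_path, dialect=config.dialect)
    markers = infer_marker_info(raw)
    matrix = digitize(raw, markers)
    report = compress_matrix(matrix, out_path, config)
    if not hasattr(out_path, "write"):
        originals = [ped_path] + ([map_path] if map_path else [])
        report.factor = compression_factor(originals, out_path)
    return report


def decompress_file(container_path, ped_path, map_path=None, *,
                    dialect: str = "ped") -> GenotypeMatrix:
    """Decode a container back to PED/MAP; atomic on failure.

    The output is written to a temporary file first and renamed into place,
    so a corrupt container never leaves partial output behind.
    """
    matrix, _header = read_container(container_path)
    raw = undigitize(matrix)
    tmp_ped = f"{ped_path}.tmp"
    tmp_map = f"{map_path}.tmp" if map_path else None
    try:
        write_ped(raw, tmp_ped, tmp_map, dialect=dialect)
        os.replace(tmp_ped, ped_path)
        if map_path:
            os.replace(tmp_map, map_path)
    except BaseException:
        for p in (tmp_ped, tmp_map):
            if p and os.path.exists(p):
                os.remove(p)
        raise
    return matrix


def roundtrip_matrix(matrix: GenotypeMatrix,
                     config: RunConfig | None = None) -> GenotypeMatrix:
    """Compress to an in-memory buffer and decode again (testing aid)."""
    import io

    buf = io.BytesIO()
    compress_matrix(matrix, buf, config)
    buf.seek(0)
    decoded, _ = read_container(buf)
    return decoded
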