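"""Default model parameters for the E. coli homology-search calculations.

Two nucleoid radii are in circulation: 0.2 µm is used for the absolute
search-time prediction, 0.3 µm for the 2D/3D speed-ratio estimate. Both are
kept as named constants rather than silently reconciled.
"""

# Nucleoid geometry (µm)
HALF_LENGTH_UM = 1.0            # L: half the pole-to-pole nucleoid length
NUCLEOID_RADIUS_UM = 0.2        # R used in the association-time prediction
NUCLEOID_RADIUS_RATIO_UM = 0.3  # R used in the 2D/3D speed-ratio estimate
REACTION_RADIUS_UM = 0.001      # r: ~1 nt reaction radius of the filament rod

# Locus diffusivity (µm²/s). Chromosomal loci are subdiffusive, so the
# effective D depends on the length scale probed: D_R at the nucleoid-radius
# scale, D_L (one order of magnitude slower) at the cell-length scale.
D_R_UM2_S = 7.0e-4
D_L_UM2_S = 7.0e-5

# Probing budget
GENOME_DSDNA_BP = 9.6e6         # ~4.8 Mb/genome x ~2 genomes per cell
FILAMENT_SSDNA_BP = 2000.0      # ssDNA length covered by the RecA filament
AVAILABLE_TIME_S = 300.0        # half of the ~10 min measured search window

# Parallelised-naive model worked example
PARALLEL_FILAMENT_BASES = 1750.0
PARALLEL_SEGMENT_BASES = 10.0

# Repair-success bookkeeping (printed single-cell counts)
REPAIRED_CELLS = 447
CELLS_WITH_TEMPLATE = 468
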