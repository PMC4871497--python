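# nlcmorph

Automated 3-D reconstruction and morphometry of the bony nasolacrimal
canal (NLC) from CT volumes.

The bony NLC is the osseous channel that carries the tear duct from the
orbit to the nasal cavity; its calibre is clinically relevant because a
narrow canal predisposes to obstruction, epiphora and dacryocystitis.
Manual CT measurements of the canal are slow and subjective, and
measuring in the axial plane systematically overestimates
cross-sectional areas whenever the canal is oblique to the scanner
axis.  `nlcmorph` implements a fully automated pipeline:

1. **read + validate** a DICOM series (geometric tag consistency:
   slice-location vs image-position spacing, canonical orientation
   cosines) — `nlcmorph.ct_io`;
2. **segment** the canal lumen per axial slice (enclosed low-HU
   component inside the bone wall, seeded and tracked across slices)
   and record each region's pixel-count area `A_k` and centroid —
   `nlcmorph.segmentation`;
3. **model the axis** from the centroid sequence `(c_1 … c_p)`: a
   polygonal interpolant and least-squares polynomials of degree
   2/3/4, `x(z) = a_0 + a_1 z + … + a_4 z^4` (and likewise `y(z)`),
   over the extended domain `[z_1 − δ/2, z_p + δ/2]`, where δ is the
   inter-slice spacing — `nlcmorph.axis_models`;
4. **measure** six lengths (axial `p·δ`, end-to-end, polygonal path,
   and three polynomial arc lengths `∫√(1 + x′² + y′²) dz`), axial and
   orthogonal sectional areas (`A_k⊥ = A_k cos β_k`, with direct
   oblique reslicing as the reference method), minimum-area size and
   craniocaudal depth, and voxel-summation volume —
   `nlcmorph.morphometry`;
5. **reconstruct** a smoothed watertight surface mesh (STL/PLY/OBJ) —
   `nlcmorph.surface_model`.

A synthetic phantom generator (`nlcmorph.phantom`) builds curved bony
tubes with analytic ground truth so every stage is testable without
clinical data.

## Worked example

Generate a phantom canal, run the full measurement pipeline and
summarise:

```sh
nlcmorph phantom scratch/demo/subj01 --slices 16 --waist
nlcmorph measure scratch/demo scratch/out --laterality left
nlcmorph report scratch/out/morphometry.csv scratch/out/stats.csv
```

which prints (one canal, so mean = median and SD is undefined; middle
rows elided):

```
               n  mean  median  sd   p25   p50   p75
variable
Vol            1 81.90   81.90 NaN 81.90 81.90 81.90
AxL            1 10.00   10.00 NaN 10.00 10.00 10.00
ExL            1 10.17   10.17 NaN 10.17 10.17 10.17
PolygL         1 10.19   10.19 NaN 10.19 10.19 10.19
Polyn3L        1 10.18   10.18 NaN 10.18 10.18 10.18
SecA           1  8.19    8.19 NaN  8.19  8.19  8.19
SecPolyn3A     1  8.04    8.04 NaN  8.04  8.04  8.04
MinSecPolyn3A  1  6.02    6.02 NaN  6.02  6.02  6.02
MinSecPolyn3D  1  4.06    4.06 NaN  4.06  4.06  4.06
```

Reading: a 16-slice canal has axial length `16 × 0.625 = 10 mm`; the
end-to-end and path lengths are slightly longer because the canal is
oblique; the axial mean area (8.19 mm²) exceeds every orthogonal mean
(≈8.04 mm²) because axial cuts of an oblique tube are elongated.  The
waisted radius profile of this phantom dips to 1.4 mm (true minimum
orthogonal area `π·1.4² ≈ 6.16 mm²` at 5.0 mm depth); the pipeline
finds 6.02 mm² at 4.06 mm — the waist is quadratically flat, so pixel
quantisation can move the argmin a slice or two.  The same API is
available from Python (`read_dicom_series`, `segment_canal`,
`compute_all`, …), and `compute_all` returns the full 22-variable set
(`Vol, AxL, ExL, PolygL, Polyn2L…MinSecPolyn4D`) per canal.

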