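# Feature catalogue

Every candidate feature, by family, with its defining formula. The same
58-feature catalogue applies to solid, cystic and mixed masses; mixed
masses repeat it on the Otsu-thresholded solid subregion under the
`solid_sub::` prefix (116 candidates total). Panels are subsets chosen by
stability selection. `feature_catalogue()` in `ovarisk.radiomics` returns
the authoritative ordered list.

Notation: I = raw intensity inside the mask, N = pixel count,
g ∈ {1..Ng} = discretized gray level, p(i,j) = normalized symmetric
co-occurrence matrix, R(g,l) = run-length matrix (Nr runs), Z(g,s) =
size-zone matrix (Nz zones). GLCM/GLRLM values are averaged over the four
2D directions; GLCM is computed per distance d ∈ {1, 2, 4} px.

## First order (prefix `fo_`)

| name | formula |
|---|---|
| fo_mean | (1/N) Σ I |
| fo_variance | (1/N) Σ (I − mean)² |
| fo_skewness | m₃ / m₂^{3/2} (0 for constant ROI) |
| fo_kurtosis | m₄ / m₂² − 3 (excess; 0 for constant ROI) |
| fo_energy | Σ I² |
| fo_entropy | −Σ p(g) log₂ p(g) over the discretized histogram |
| fo_p10, fo_p90 | 10th / 90th intensity percentiles |
| fo_iqr | 75th − 25th percentile |
| fo_range | max I − min I |
| fo_mad | (1/N) Σ \|I − mean\| |
| fo_rms | sqrt((1/N) Σ I²) |
| fo_uniformity | Σ p(g)² |

## Shape (prefix `shape_`, physical units from pixel spacing)

| name | formula |
|---|---|
| shape_area | N · pixel area (mm²) |
| shape_perimeter | Crofton perimeter estimate, 4 directions (mm) |
| shape_equivalent_diameter | 2 sqrt(area / π) |
| shape_major_axis, shape_minor_axis | inertia-ellipse axis lengths |
| shape_eccentricity | ellipse eccentricity ∈ [0, 1) |
| shape_circularity | 4π area / perimeter² |
| shape_solidity | N / (convex hull area of the pixel-corner cloud) |
| shape_feret_max | maximum Feret (caliper) diameter |

## GLCM (prefix `glcm_d{1,2,4}_`)

With μ = Σ i p(i,j) and σ² the marginal variance:

| name | formula |
|---|---|
| contrast | Σ p(i,j) (i−j)² |
| dissimilarity | Σ p(i,j) \|i−j\| |
| homogeneity | Σ p(i,j) / (1 + \|i−j\|) (inverse difference) |
| asm | Σ p(i,j)² (angular second moment) |
| correlation | Σ p(i,j)(i−μ)(j−μ) / σ² (1 if σ = 0) |
| joint_entropy | −Σ p(i,j) log₂ p(i,j) |
| cluster_shade | Σ p(i,j) (i+j−2μ)³ |
| cluster_prominence | Σ p(i,j) (i+j−2μ)⁴ |

## GLRLM (prefix `glrlm_`)

| name | formula |
|---|---|
| sre | (1/Nr) Σ R(g,l)/l² |
| lre | (1/Nr) Σ R(g,l) l² |
| gln | (1/Nr) Σ_g (Σ_l R)² |
| rln | (1/Nr) Σ_l (Σ_g R)² |
| run_percentage | Nr / N |
| lglre | (1/Nr) Σ R(g,l)/g² |
| hglre | (1/Nr) Σ R(g,l) g² |

## GLSZM (prefix `glszm_`, 8-connected zones)

| name | formula |
|---|---|
| sze | (1/Nz) Σ Z(g,s)/s² |
| lze | (1/Nz) Σ Z(g,s) s² |
| szn | (1/Nz) Σ_s (Σ_g Z)² |
| gln | (1/Nz) Σ_g (Σ_s Z)² |
| zone_percentage | Nz / N |
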