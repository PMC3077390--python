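# Multi-ROI bundle-extraction protocol for real atlas-space data
# (1 mm isotropic single-subject DTI atlas, 181 x 217 x 181 grid).
#
# Slice indices follow the published delineation protocol for the fornix and
# cingulum: each bundle keeps exactly the streamlines that penetrate every
# listed ROI (AND logic).  Plane kinds fix one axis: sagittal = x,
# coronal = y (posterior-anterior), axial = z (inferior-superior).
# `region: null` keeps the whole slice; hemisphere splits can be added by
# restricting the sagittal (first in-plane) range.
#
# The cingulum in the cingulate gyrus (CGC) is additionally partitioned into
# anterior / middle / posterior sub-bundles at two coronal planes where the
# corpus-callosum fiber orientation changes.

atlas:
  grid_shape: [181, 217, 181]
  voxel_size_mm: [1.0, 1.0, 1.0]

bundles:
  fornix:
    orientation: hippocampus_to_thalamus
    rois:
      - {kind: coronal, slice_index: 150, region: null,
         note: most anterior coronal plane where the body of the fornix is visible}
      - {kind: axial, slice_index: 108, region: null,
         note: axial plane including the tail of the hippocampus}
  cgh:
    orientation: splenium_to_hippocampus
    rois:
      - {kind: axial, slice_index: 126, region: null,
         note: axial plane where the cingulum turns anteriorly above the splenium}
      - {kind: coronal, slice_index: 125, region: null,
         note: coronal plane anterior to the pons}
  cgc:
    orientation: anterior_to_posterior
    rois:
      - {kind: axial, slice_index: 126, region: null,
         note: axial plane where the hippocampal cingulum ends}
      - {kind: coronal, slice_index: 183, region: null,
         note: coronal slice most anterior to the corpus callosum}
    partition:
      coronal_slices: [127, 162]
      note: anterior / middle / posterior split where the corpus-callosum
        fiber orientation changes
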