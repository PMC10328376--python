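# Illustrative calibrated kinetics for the PhuZ spindle model.
#
# Fitted with phuzsim.calibrate against the package's synthetic control
# dataset (3.5 um cells) so that a 3.5 um cell centers its phage nucleus
# efficiently within 30 min while 2-4x elongated cells do not. These are
# NOT published measurements; treat them as a documented working point.
#
# The nucleus diffusion coefficient corresponds to a 1 um Stokes radius
# in an effective cytoplasmic viscosity of ~2 Pa s at 310 K (the
# Stokes-Einstein helper with water viscosity gives 0.227 um^2/s, far
# too mobile for a chromosome-scale object in crowded cytoplasm).
#
# Working point: net growth v_poly - v_depoly = 0.03 um/s and mean
# growth interval t_cat = 50 s give a polymerized reach of ~1.5 um per
# growth phase, just above the 1.25 um pole-to-nucleus-face distance of
# a 3.5 um cell -- the condition for tight centering. Catastrophic
# shrinkage (v_cat = 0.4 um/s over ~8 s) fully resets a filament, so
# in 2-4x elongated cells the reach falls short of the nucleus and
# centering collapses.
kinetics:
  v_poly_mean: 0.045
  v_poly_sd: 0.005
  v_depoly_mean: 0.015
  v_depoly_sd: 0.002
  v_cat_mean: 0.4
  v_cat_sd: 0.05
  t_cat_mean: 50.0
  t_cat_sd: 3.0
  t_rec_mean: 8.0
  t_rec_sd: 3.0
cell:
  length: 3.5
  nucleus_radius: 0.5
  nucleus_diffusion_coeff: 0.0001
  nucleus_init_frac: 0.9
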