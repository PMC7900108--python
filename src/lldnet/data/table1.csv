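item,hoa_mean,hoa_sd,apos_mean,apos_sd,aneg_mean,aneg_sd,f_printed,t_hoa_apos,t_hoa_aneg,t_apos_aneg,f_consistent,t_hoa_apos_consistent,t_hoa_aneg_consistent,t_apos_aneg_consistent
age,68.86,4.6,76.85,7.3,76.07,5.41,12.356,-4.359,-4.892,0.439,1,1,1,1
education,13.33,4.23,6.92,4.42,6.37,4.36,17.94,5.037,5.557,0.458,1,1,1,1
geriatric_depression_scale,8.71,4.22,13.12,6.78,15.7,6.37,8.06,-2.594,-4.339,-1.434,1,1,1,1
mmse,28.95,0.92,20.88,3.86,22.74,4.85,28.682,9.345,5.777,-1.538,1,1,1,1
word_list_learning,21.86,3.18,9.96,3.4,11.63,4.1,71.624,12.268,9.432,-1.61,1,1,1,1
word_list_learning_z,1.31,0.76,-1.36,0.65,-0.98,0.83,83.036,12.958,9.805,-1.843,1,1,1,1
word_list_recall,7.76,1.45,1.38,1.42,2.63,2.06,90.673,15.205,9.7,2.555,1,1,1,1
word_list_recall_z,0.93,0.74,2.05,0.64,-1.42,0.88,95.745,14.783,9.819,2.958,0,0,1,0
word_list_recognition,9.57,0.81,5.58,3.0,6.22,2.99,15.677,5.926,4.98,-0.785,1,1,1,1
word_list_recognition_z,0.39,0.59,-1.88,1.97,-1.43,1.72,12.829,5.088,4.632,-0.896,1,1,1,0
constructional_praxis,10.14,0.96,8.58,2.37,7.96,1.83,8.385,2.84,4.946,1.058,1,1,1,1
constructional_praxis_z,-0.06,0.72,0.04,0.88,-0.53,1.48,1.976,-0.454,1.315,1.698,1,0,0,1
constructional_praxis_recall,7.43,2.42,1.58,1.98,2.81,2.2,44.722,9.114,6.896,2.148,1,1,1,1
constructional_praxis_recall_z,0.086,0.84,-1.48,0.93,-0.64,0.95,17.236,5.97,2.774,-3.236,1,1,1,1
trail_making_a,1.0,0.0,0.85,0.37,0.78,0.42,2.634,1.912,2.398,-0.626,0,0,1,0
trail_making_a_z,1.38,0.63,-0.01,0.99,-0.66,1.46,19.426,5.458,5.858,1.695,0,0,0,0
trail_making_a_seconds,40.48,12.9,113.14,58.22,138.14,86.32,14.784,-5.587,-5.128,-1.118,1,1,1,0
boston_naming,12.76,1.58,9.23,3.01,8.7,2.84,16.128,4.856,5.873,0.656,1,1,1,1
boston_naming_z,0.75,0.61,-0.08,0.95,-0.17,0.84,8.649,3.469,4.265,0.395,0,1,1,0
digit_span_forward,6.52,1.25,4.46,0.9,4.0,0.83,41.87,6.558,8.384,1.934,1,1,1,1
digit_span_backward,4.47,1.17,2.73,0.67,2.63,0.88,29.478,6.444,6.243,0.469,1,1,1,0
cowat_animal,16.71,4.28,8.77,2.75,9.56,3.33,36.372,7.712,6.521,-0.935,1,1,1,1
cowat_animal_z,0.06,0.86,-1.27,0.67,-1.09,0.89,17.875,5.952,4.503,-0.835,1,1,1,1
cowat_market,20.57,6.66,10.88,4.26,10.59,4.26,28.523,6.051,6.308,0.25,1,1,1,1
cowat_market_z,0.38,1.2,-0.65,0.77,-0.67,0.93,8.872,3.583,3.446,0.089,0,1,1,0
cowat_lexical_g,9.38,3.61,4.65,3.23,2.67,2.82,25.332,4.586,6.991,2.247,0,0,0,0
cowat_lexical_o,10.24,4.09,4.35,3.2,2.79,2.87,29.38,5.349,7.14,1.756,0,0,0,0
cowat_lexical_s,10.19,4.34,5.17,3.7,3.17,3.09,20.889,4.135,6.311,2.022,0,0,0,0
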