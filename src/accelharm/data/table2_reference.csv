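,MAI_ankle,MAI_chest,MAI_hip,MAI_thigh,MAI_upper_arm,MAI_wrist,ENMO_ankle,ENMO_chest,ENMO_hip,ENMO_thigh,ENMO_upper_arm,ENMO_wrist,MAD_ankle,MAD_chest,MAD_hip,MAD_thigh,MAD_upper_arm,MAD_wrist,CPM_ankle,CPM_chest,CPM_hip,CPM_thigh,CPM_upper_arm,CPM_wrist
MAI_ankle,1.0,0.91,0.95,0.97,0.83,0.71,0.97,0.89,0.91,0.92,0.8,0.75,0.97,0.91,0.93,0.95,0.85,0.76,0.98,0.78,0.86,0.92,0.74,0.59
MAI_chest,0.91,1.0,0.98,0.95,0.94,0.86,0.92,0.97,0.95,0.93,0.9,0.87,0.89,0.97,0.96,0.93,0.93,0.89,0.91,0.9,0.9,0.89,0.86,0.74
MAI_hip,0.95,0.98,1.0,0.98,0.92,0.82,0.94,0.95,0.98,0.95,0.88,0.84,0.93,0.97,0.98,0.95,0.92,0.86,0.94,0.86,0.92,0.91,0.82,0.69
MAI_thigh,0.97,0.95,0.98,1.0,0.89,0.78,0.96,0.93,0.95,0.97,0.86,0.81,0.95,0.95,0.96,0.97,0.9,0.83,0.96,0.82,0.89,0.94,0.8,0.65
MAI_upper_arm,0.83,0.94,0.92,0.89,1.0,0.95,0.84,0.91,0.9,0.88,0.96,0.92,0.8,0.91,0.9,0.85,0.96,0.94,0.84,0.83,0.82,0.83,0.95,0.85
MAI_wrist,0.71,0.86,0.82,0.78,0.95,1.0,0.73,0.83,0.81,0.78,0.86,0.94,0.68,0.83,0.8,0.75,0.87,0.95,0.72,0.76,0.73,0.73,0.88,0.94
ENMO_ankle,0.97,0.92,0.94,0.96,0.84,0.73,1.0,0.92,0.94,0.96,0.84,0.78,0.95,0.93,0.94,0.96,0.86,0.78,0.95,0.76,0.83,0.88,0.74,0.6
ENMO_chest,0.89,0.97,0.95,0.93,0.91,0.83,0.92,1.0,0.97,0.95,0.9,0.87,0.88,0.98,0.97,0.93,0.92,0.87,0.91,0.81,0.85,0.86,0.81,0.68
ENMO_hip,0.91,0.95,0.98,0.95,0.9,0.81,0.94,0.97,1.0,0.96,0.89,0.85,0.9,0.97,0.98,0.95,0.91,0.85,0.92,0.8,0.86,0.87,0.8,0.67
ENMO_thigh,0.92,0.93,0.95,0.97,0.88,0.78,0.96,0.95,0.96,1.0,0.88,0.83,0.91,0.95,0.95,0.96,0.89,0.83,0.92,0.78,0.83,0.88,0.78,0.64
ENMO_upper_arm,0.8,0.9,0.88,0.86,0.96,0.86,0.84,0.9,0.89,0.88,1.0,0.89,0.78,0.9,0.88,0.84,0.94,0.88,0.82,0.75,0.76,0.8,0.89,0.72
ENMO_wrist,0.75,0.87,0.84,0.81,0.92,0.94,0.78,0.87,0.85,0.83,0.89,1.0,0.73,0.86,0.84,0.8,0.87,0.93,0.77,0.74,0.73,0.75,0.82,0.84
MAD_ankle,0.97,0.89,0.93,0.95,0.8,0.68,0.95,0.88,0.9,0.91,0.78,0.73,1.0,0.91,0.93,0.96,0.85,0.74,0.95,0.76,0.84,0.89,0.7,0.55
MAD_chest,0.91,0.97,0.97,0.95,0.91,0.83,0.93,0.98,0.97,0.95,0.9,0.86,0.91,1.0,0.99,0.94,0.94,0.88,0.92,0.83,0.87,0.87,0.81,0.68
MAD_hip,0.93,0.96,0.98,0.96,0.9,0.8,0.94,0.97,0.98,0.95,0.88,0.84,0.93,0.99,1.0,0.96,0.92,0.85,0.93,0.82,0.88,0.88,0.8,0.66
MAD_thigh,0.95,0.93,0.95,0.97,0.85,0.75,0.96,0.93,0.95,0.96,0.84,0.8,0.96,0.94,0.96,1.0,0.88,0.8,0.95,0.79,0.86,0.9,0.76,0.61
MAD_upper_arm,0.85,0.93,0.92,0.9,0.96,0.87,0.86,0.92,0.91,0.89,0.94,0.87,0.85,0.94,0.92,0.88,1.0,0.93,0.87,0.8,0.82,0.84,0.88,0.74
MAD_wrist,0.76,0.89,0.86,0.83,0.94,0.95,0.78,0.87,0.85,0.83,0.88,0.93,0.74,0.88,0.85,0.8,0.93,1.0,0.77,0.77,0.76,0.77,0.85,0.84
CPM_ankle,0.98,0.91,0.94,0.96,0.84,0.72,0.95,0.91,0.92,0.92,0.82,0.77,0.95,0.92,0.93,0.95,0.87,0.77,1.0,0.77,0.85,0.94,0.75,0.59
CPM_chest,0.78,0.9,0.86,0.82,0.83,0.76,0.76,0.81,0.8,0.78,0.75,0.74,0.76,0.83,0.82,0.79,0.8,0.77,0.77,1.0,0.92,0.81,0.81,0.7
CPM_hip,0.86,0.9,0.92,0.89,0.82,0.73,0.83,0.85,0.86,0.83,0.76,0.73,0.84,0.87,0.88,0.86,0.82,0.76,0.85,0.92,1.0,0.88,0.77,0.65
CPM_thigh,0.92,0.89,0.91,0.94,0.83,0.73,0.88,0.86,0.87,0.88,0.8,0.75,0.89,0.87,0.88,0.9,0.84,0.77,0.94,0.81,0.88,1.0,0.77,0.62
CPM_upper_arm,0.74,0.86,0.82,0.8,0.95,0.88,0.74,0.81,0.8,0.78,0.89,0.82,0.7,0.81,0.8,0.76,0.88,0.85,0.75,0.81,0.77,0.77,1.0,0.84
CPM_wrist,0.59,0.74,0.69,0.65,0.85,0.94,0.6,0.68,0.67,0.64,0.72,0.84,0.55,0.68,0.66,0.61,0.74,0.84,0.59,0.7,0.65,0.62,0.84,1.0
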