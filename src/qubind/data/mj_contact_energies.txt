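# Miyazawa-Jernigan residue-residue contact energies, kBT units
A R N D C Q E G H I L K M F P S T W Y V
A  -2.72  -1.83  -1.84  -1.70  -3.57  -1.89  -1.51  -2.31  -2.41  -4.58  -4.91  -1.31  -3.94  -4.81  -2.03  -2.01  -2.32  -3.82  -3.36  -4.04
R  -1.83  -1.55  -1.64  -2.29  -2.57  -1.80  -2.27  -1.72  -2.16  -3.63  -4.03  -0.59  -3.12  -3.98  -1.70  -1.62  -1.90  -3.41  -3.16  -3.07
N  -1.84  -1.64  -1.68  -1.68  -2.59  -1.71  -1.51  -1.74  -2.08  -3.24  -3.74  -1.21  -2.95  -3.75  -1.53  -1.58  -1.88  -3.07  -2.76  -2.83
D  -1.70  -2.29  -1.68  -1.21  -2.41  -1.46  -1.02  -1.59  -2.32  -3.17  -3.40  -1.68  -2.57  -3.48  -1.33  -1.63  -1.80  -2.84  -2.76  -2.48
C  -3.57  -2.57  -2.59  -2.41  -5.44  -2.85  -2.27  -3.16  -3.60  -5.50  -5.83  -1.95  -4.99  -5.80  -3.07  -2.86  -3.11  -4.95  -4.16  -4.96
Q  -1.89  -1.80  -1.71  -1.46  -2.85  -1.54  -1.42  -1.66  -1.98  -3.67  -4.04  -1.29  -3.30  -4.10  -1.73  -1.49  -1.90  -3.11  -2.97  -3.07
E  -1.51  -2.27  -1.51  -1.02  -2.27  -1.42  -0.91  -1.22  -2.15  -3.27  -3.59  -1.80  -2.89  -3.56  -1.26  -1.48  -1.74  -2.99  -2.79  -2.67
G  -2.31  -1.72  -1.74  -1.59  -3.16  -1.66  -1.22  -2.24  -2.15  -3.78  -4.16  -1.15  -3.39  -4.13  -1.87  -1.82  -2.08  -3.42  -3.01  -3.38
H  -2.41  -2.16  -2.08  -2.32  -3.60  -1.98  -2.15  -2.15  -3.05  -4.14  -4.54  -1.35  -3.98  -4.77  -2.25  -2.11  -2.42  -3.98  -3.52  -3.58
I  -4.58  -3.63  -3.24  -3.17  -5.50  -3.67  -3.27  -3.78  -4.14  -6.54  -7.04  -3.01  -6.02  -6.84  -3.76  -3.52  -4.03  -5.78  -5.25  -6.05
L  -4.91  -4.03  -3.74  -3.40  -5.83  -4.04  -3.59  -4.16  -4.54  -7.04  -7.37  -3.37  -6.41  -7.28  -4.20  -3.92  -4.34  -6.14  -5.67  -6.48
K  -1.31  -0.59  -1.21  -1.68  -1.95  -1.29  -1.80  -1.15  -1.35  -3.01  -3.37  -0.12  -2.48  -3.36  -0.97  -1.05  -1.31  -2.69  -2.60  -2.49
M  -3.94  -3.12  -2.95  -2.57  -4.99  -3.30  -2.89  -3.39  -3.98  -6.02  -6.41  -2.48  -5.46  -6.56  -3.45  -3.03  -3.51  -5.55  -4.91  -5.32
F  -4.81  -3.98  -3.75  -3.48  -5.80  -4.10  -3.56  -4.13  -4.77  -6.84  -7.28  -3.36  -6.56  -7.26  -4.25  -4.02  -4.28  -6.16  -5.66  -6.29
P  -2.03  -1.70  -1.53  -1.33  -3.07  -1.73  -1.26  -1.87  -2.25  -3.76  -4.20  -0.97  -3.45  -4.25  -1.75  -1.57  -1.90  -3.73  -3.19  -3.32
S  -2.01  -1.62  -1.58  -1.63  -2.86  -1.49  -1.48  -1.82  -2.11  -3.52  -3.92  -1.05  -3.03  -4.02  -1.57  -1.67  -1.96  -2.99  -2.78  -3.05
T  -2.32  -1.90  -1.88  -1.80  -3.11  -1.90  -1.74  -2.08  -2.42  -4.03  -4.34  -1.31  -3.51  -4.28  -1.90  -1.96  -2.12  -3.22  -3.01  -3.46
W  -3.82  -3.41  -3.07  -2.84  -4.95  -3.11  -2.99  -3.42  -3.98  -5.78  -6.14  -2.69  -5.55  -6.16  -3.73  -2.99  -3.22  -5.06  -4.66  -5.18
Y  -3.36  -3.16  -2.76  -2.76  -4.16  -2.97  -2.79  -3.01  -3.52  -5.25  -5.67  -2.60  -4.91  -5.66  -3.19  -2.78  -3.01  -4.66  -4.17  -4.62
V  -4.04  -3.07  -2.83  -2.48  -4.96  -3.07  -2.67  -3.38  -3.58  -6.05  -6.48  -2.49  -5.32  -6.29  -3.32  -3.05  -3.46  -5.18  -4.62  -5.52
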