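gene	logFC	t	p	s2_post
g001	 1.0904496	 6.1701755275043	4.62153060909e-05	0.0780829415759
g002	 1.1296902	 6.7786530908513	1.87852627015e-05	0.0694339566283
g003	 1.1636680	 7.6663205157599	5.50650951234e-06	0.0576002339384
g004	 1.1793076	 8.2633215037124	2.54435486864e-06	0.0509195905416
g005	 0.8524324	 5.7653488093268	8.65165516151e-05	0.0546523360551
g006	 0.5748658	 4.8061774175522	4.18843745949e-04	0.0357662457482
g007	 0.8717080	 6.5632383253924	2.56896852990e-05	0.0441007243351
g008	 0.8461626	 6.2517240321391	4.08436009512e-05	0.0457981634343
g009	 1.1241346	 3.3122908863540	6.13191507216e-03	0.2879517351756
g010	 1.4212292	 5.0867031380804	2.60601085528e-04	0.1951620928135
g011	 0.1172502	 0.6870706932514	5.04990741076e-01	0.0728055261076
g012	 0.1400434	 0.9280221060583	3.71533974103e-01	0.0569309797544
g013	 0.1913050	 0.9161425577658	3.77485205489e-01	0.1090100489688
g014	-0.2258272	-1.0873657716129	2.98055802404e-01	0.1078303940295
g015	 0.0515318	 0.3364023708712	7.42328277574e-01	0.0586641169788
g016	 0.0422994	 0.1873388719518	8.54498842423e-01	0.1274537509607
g017	 0.2153714	 1.0187440792897	3.28257257959e-01	0.1117341361037
g018	-0.0072108	-0.0715873690628	9.44099660962e-01	0.0253649555300
g019	 0.1025572	 0.7457242784652	4.70069988925e-01	0.0472841682575
g020	-0.1686610	-1.2311100269926	2.41669334734e-01	0.0469219025873
g021	-0.1279852	-0.9359919324074	3.67578334734e-01	0.0467428620610
g022	-0.7401840	-2.8289813444951	1.50940365722e-02	0.1711430343301
g023	 0.0200186	 0.1422671676780	8.89209846927e-01	0.0494991842095
g024	-0.0818994	-0.8847877366524	3.93509453900e-01	0.0214201870871
g025	-0.3354580	-1.3697317670950	1.95647353894e-01	0.1499495819117
g026	 0.1627886	 1.2444688291531	2.36887395075e-01	0.0427779470830
g027	 0.1259380	 1.0366615552876	3.20162477501e-01	0.0368960272912
g028	 0.1043772	 0.8436110402183	4.15249342511e-01	0.0382707333332
g029	-0.1275516	-0.5907471407316	5.65558462209e-01	0.1165490059042
g030	 0.0893012	 0.4129617342475	6.86856699689e-01	0.1169055087656
g031	 0.2096348	 1.0749116665346	3.03376625123e-01	0.0950870146644
g032	 0.0271818	 0.1839492957378	8.57099206148e-01	0.0545883761066
g033	 0.0041494	 0.0389934353905	9.69531449214e-01	0.0283092012560
g034	 0.2014476	 1.0607640073888	3.09506977415e-01	0.0901626470162
g035	-0.0888500	-0.2553572593700	8.02735050550e-01	0.3026623889729
g036	-0.3183758	-2.2906844390493	4.07088830908e-02	0.0482935994746
g037	 0.0179580	 0.1199234284450	9.06511530453e-01	0.0560593259205
g038	 0.0269870	 0.1265128668492	9.01403423846e-01	0.1137574458336
g039	 0.0227854	 0.2012320408233	8.43859443205e-01	0.0320522897046
g040	 0.2854676	 2.1741562779585	5.02338731968e-02	0.0430994909345
g041	 0.0900742	 0.8122644559217	4.32326497472e-01	0.0307429782176
g042	-0.0793478	-0.4161827572442	6.84561330447e-01	0.0908744138099
g043	-0.1012208	-0.9237649932645	3.73659054913e-01	0.0300162572591
g044	-0.0480320	-0.4258395662616	6.77699432239e-01	0.0318060200344
g045	 0.0134746	 0.1019250476792	9.20485362445e-01	0.0436928049188
g046	-0.3448240	-2.8300351390709	1.50644476686e-02	0.0371151588441
g047	-0.1011022	-0.9461670851777	3.62571263393e-01	0.0285447043254
g048	 0.1821472	 1.5288552503497	1.52005906853e-01	0.0354856095575
g049	-0.1957474	-0.4984663415505	6.27090446044e-01	0.3855319159382
g050	-0.4175384	-1.8979908456273	8.18002248953e-02	0.1209886489776
g051	 0.0436140	 0.4414423568615	6.66676151638e-01	0.0244030350375
g052	 0.1661652	 0.9100951182462	3.80540084920e-01	0.0833386744133
g053	-0.0037600	-0.0278760070401	9.78215424195e-01	0.0454835723451
g054	-0.0027012	-0.0220176688602	9.82792698033e-01	0.0376279726113
g055	 0.1918210	 1.4689078833428	1.67364775285e-01	0.0426327342386
g056	-0.2455438	-1.9759842473897	7.14017430028e-02	0.0386038836342
g057	 0.0818338	 0.4267052680648	6.77085744158e-01	0.0919495135712
g058	-0.1012808	-0.4236495217731	6.79253011483e-01	0.1428830834707
g059	 0.2106354	 1.3907887991623	1.89331225828e-01	0.0573429938412
g060	 0.2373706	 1.4159198347541	1.82015782747e-01	0.0702613568913
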